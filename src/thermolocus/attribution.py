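"""Analysis machinery on a trained model: stripe-border decomposition,
per-TF activation shares, in-silico fragment assays, and trans perturbations.

The model is columnwise in the axis: the prediction at position i depends
only on the TF concentrations at position i.  Numerical derivatives with
respect to one factor's concentration are therefore computed for all
positions at once by shifting that factor's whole profile column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .competition import ModelOutput, predict, window_adaptors
from .io import AccessibilityMask, LocusSequence, ProfileTable
from .params import ParameterSet
from .synthetic import ProblemBundle


@dataclass(frozen=True)
class BorderContribution:
    """Per-TF, per-position first-order contribution to the change in
    output: (dR/d[A]) * d[A], plus the raw derivative table."""

    tf_names: tuple[str, ...]
    contributions: dict[str, np.ndarray]
    derivatives: dict[str, np.ndarray]
    delta: dict[str, np.ndarray]


@dataclass(frozen=True)
class ActivationShare:
    """Time-weighted adaptors recruited per TF, and the percent-of-max view."""

    tf_names: tuple[str, ...]
    N_a: dict[str, np.ndarray]
    percent: dict[str, np.ndarray]


@dataclass(frozen=True)
class FragmentAssay:
    standardized: np.ndarray   # max = 1 (flat zero if the fragment is silent)
    output: ModelOutput


def _predict(params, bundle: ProblemBundle, profiles=None,
             mask: AccessibilityMask | None = None) -> ModelOutput:
    return predict(bundle.seq, bundle.pwms, params,
                   profiles if profiles is not None else bundle.profiles,
                   mask=mask, mode=bundle.mode, threshold=bundle.threshold)


def derivative_profile(params: ParameterSet, bundle: ProblemBundle, tf: str,
                       h: float = 1e-3,
                       mask: AccessibilityMask | None = None) -> np.ndarray:
    """dR/d[tf] at every axis position by numerical differentiation.

    Uses the symmetric difference quotient where the concentration is
    positive (shrinking the backward step where [tf] < h so concentrations
    stay non-negative) and Newton's forward quotient where it is zero.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    profiles = bundle.profiles
    a = profiles[tf]
    up = _predict(params, bundle, profiles.replace(tf, a + h), mask).mRNA_pred
    h_back = np.minimum(h, a)                      # 0 where [tf] = 0
    down = _predict(params, bundle, profiles.replace(tf, a - h_back), mask).mRNA_pred
    return (up - down) / (h + h_back)


def rate_derivative(params: ParameterSet, bundle: ProblemBundle, tf: str,
                    position: int, h: float = 1e-3,
                    mask: AccessibilityMask | None = None) -> float:
    """dR_i/d[tf]_i at one axis position (index into the profile grid)."""
    return float(derivative_profile(params, bundle, tf, h, mask)[position])


def derivative_convergence(params: ParameterSet, bundle: ProblemBundle, tf: str,
                           exponents=range(-1, -12, -1),
                           mask: AccessibilityMask | None = None) -> dict[float, np.ndarray]:
    """Derivative estimates over a sweep of h = 10**e, as a robustness check."""
    return {10.0 ** e: derivative_profile(params, bundle, tf, 10.0 ** e, mask)
            for e in exponents}


def border_contributions(params: ParameterSet, bundle: ProblemBundle,
                         h: float = 1e-3, delta_mode: str = "central",
                         mask: AccessibilityMask | None = None) -> BorderContribution:
    """Decompose the spatial change in output into per-TF terms.

    The concentration change at position i is the central difference
    ([A]_{i+1} - [A]_{i-1}) / 2 (one-sided at the ends).  ``delta_mode=
    "literal_average"`` instead uses the adjacent-position average
    ([A]_{i-1} + [A]_{i+1}) / 2, kept for auditability.
    """
    profiles = bundle.profiles
    if profiles.n_positions < 3:
        raise ValueError("need at least 3 axis positions")
    if delta_mode not in ("central", "literal_average"):
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    names = tuple(n for n in profiles.names() if n in params.tfs)
    contributions, derivatives, deltas = {}, {}, {}
    for tf in names:
        d = derivative_profile(params, bundle, tf, h, mask)
        a = profiles[tf]
        if delta_mode == "central":
            da = np.gradient(a)                    # central, one-sided ends
        else:
            da = np.empty_like(a)
            da[1:-1] = (a[:-2] + a[2:]) / 2.0
            da[0], da[-1] = a[1] / 2.0, a[-2] / 2.0
        derivatives[tf] = d
        deltas[tf] = da
        contributions[tf] = d * da
    return BorderContribution(names, contributions, derivatives, deltas)


def activation_shares(params: ParameterSet, bundle: ProblemBundle,
                      mask: AccessibilityMask | None = None) -> ActivationShare:
    """Time-weighted adaptor counts per TF: N_a = sum_m N[m; a] * T[m],
    reported as 100 * N_a / max_a N_a per position (competition mode)."""
    if bundle.mode != "competition":
        raise ValueError("activation shares are defined in competition mode")
    out = _predict(params, bundle, mask=mask)
    sites, ea = out.sites, out.activation
    alpha = params.globals_.alpha
    L = bundle.seq.length
    N_a: dict[str, np.ndarray] = {}
    for tf in params.tfs:
        sel = np.array([s.tf_name == tf for s in sites], dtype=bool)
        if not sel.any():
            N_a[tf] = np.zeros(out.T.shape[1])
            continue
        ea_tf = type(ea)(f_act=ea.f_act, f_rep=ea.f_rep,
                         F=np.where(sel[:, None], ea.F, 0.0))
        N_tf = window_adaptors(ea_tf, sites, params, alpha, L)
        N_a[tf] = (N_tf * out.T).sum(axis=0)
    stacked = np.vstack(list(N_a.values()))
    peak = stacked.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = {tf: np.where(peak > 0, 100.0 * v / peak, 0.0)
                   for tf, v in N_a.items()}
    return ActivationShare(tuple(N_a), N_a, percent)


def fragment_assay(params: ParameterSet, fragment: LocusSequence, pwms,
                   profiles: ProfileTable, mask: AccessibilityMask | None = None,
                   mode: str = "competition", threshold: float = 0.0) -> FragmentAssay:
    """Predict the rate a fragment drives on its own, standardised to max 1
    (the in-silico reporter assay); the raw output is kept alongside."""
    out = predict(fragment, pwms, params, profiles, mask=mask, mode=mode,
                  threshold=threshold)
    peak = out.mRNA_pred.max()
    standardized = out.mRNA_pred / peak if peak > 0 else np.zeros_like(out.mRNA_pred)
    return FragmentAssay(standardized, out)


def perturb_trans(profiles: ProfileTable, edits) -> ProfileTable:
    """Apply trans-environment edits: (tf, "scale", factor),
    (tf, "set_uniform", value) or (tf, "zero"); returns an edited copy."""
    table = profiles
    for edit in edits:
        tf, op = edit[0], edit[1]
        if tf not in table:
            raise KeyError(f"unknown TF {tf!r}")
        if op == "scale":
            table = table.replace(tf, table[tf] * float(edit[2]))
        elif op == "set_uniform":
            table = table.replace(tf, np.full(table.n_positions, float(edit[2])))
        elif op == "zero":
            table = table.replace(tf, np.zeros(table.n_positions))
        else:
            raise ValueError(f"unknown operation {op!r}")
    return table
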