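"""Enhancer competition: sliding windows of DNA compete for promoter time.

Every alpha-bp window [m, m+alpha) of the locus — window starts run from
-alpha to l-1 in single-nucleotide steps, l + alpha windows in all — recruits

    N[m] = sum over sites k with footprint midpoint in the window of F_k * E_A,

transcriptional adaptors.  A window engaged with the promoter drives
transcription at the diffusion-limited Arrhenius rate

    R[m] = Rmax / (1 + exp(theta - N[m])),

and holds the promoter for the time fraction

    T[m] = beta * N[m] / (1 + sum_n beta * N[n]),

so that the locus output is the frequency-weighted sum

    R_total = sum_m R[m] * T[m].

Predicted mRNA is proportional to R_total with the data scale carried by
Rmax.  In ``no_competition`` mode a single window spans the whole sequence
and R_total = R of that window (no T weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .context import ContextConfig, EffectiveActivation, effective_activation
from .io import AccessibilityMask, LocusSequence, ProfileTable
from .occupancy import CooperativitySpec, OccupancyTable, per_position_occupancy
from .params import ParameterSet
from .sites import BindingSite, apply_mask, scan_all, site_weights


@dataclass(frozen=True)
class ModelOutput:
    """Prediction for one locus: per-position rate plus the window ledger."""

    R_total: np.ndarray                      # (P,)
    mRNA_pred: np.ndarray                    # (P,), == R_total (scale in Rmax)
    contribution_map: np.ndarray             # (n_windows, P) of R * T
    window_starts: np.ndarray                # 0-based window starts
    N: np.ndarray                            # (n_windows, P) adaptor counts
    R: np.ndarray                            # (n_windows, P) window rates
    T: np.ndarray                            # (n_windows, P) time fractions
    mode: str = "competition"
    sites: tuple[BindingSite, ...] = ()
    occupancy: OccupancyTable | None = field(default=None, compare=False)
    activation: EffectiveActivation | None = field(default=None, compare=False)


def n_windows(locus_length: int, alpha: int) -> int:
    """Number of alpha-bp windows over a locus of length l: l + alpha."""
    return locus_length + alpha


def window_starts(locus_length: int, alpha: int) -> np.ndarray:
    return np.arange(-alpha, locus_length)


def window_adaptors(ea: EffectiveActivation, sites, params: ParameterSet,
                    alpha: int, locus_length: int) -> np.ndarray:
    """N[m, x] via sliding prefix sums, O(l + n) per axis position.

    A site belongs to the windows whose half-open interval covers its
    footprint midpoint — exactly alpha windows each.
    """
    if ea.F is None:
        raise ValueError("effective activation F not computed (run quench first)")
    n_w = n_windows(locus_length, alpha)
    P = ea.F.shape[1]
    delta = np.zeros((n_w + 1, P))
    for k, site in enumerate(sites):
        e_a = params.tfs[site.tf_name].E_A
        if e_a == 0.0:
            continue
        v = ea.F[k] * e_a
        # window start m0 covers mid iff m0 <= mid < m0 + alpha;
        # with index w = m0 + alpha: w in [floor(mid)+1, floor(mid)+alpha]
        w1 = int(np.floor(site.midpoint)) + 1
        delta[w1] += v
        delta[w1 + alpha] -= v
    N = np.cumsum(delta[:-1], axis=0)
    # clip tiny negative residue from cancellation
    np.maximum(N, 0.0, out=N)
    return N


def window_rate(N: np.ndarray, theta: float, Rmax: float) -> np.ndarray:
    """R = Rmax / (1 + exp(theta - N)), elementwise; increasing in N."""
    return Rmax / (1.0 + np.exp(theta - N))


def window_time(N: np.ndarray, beta: float) -> np.ndarray:
    """T[m] = beta N[m] / (1 + sum_n beta N[n]), per axis position."""
    S = beta * N.sum(axis=0, keepdims=True)
    return beta * N / (1.0 + S)


def locus_rate(R: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """R_total[x] = sum_m R[m, x] T[m, x]; also returns the R*T map."""
    if R.shape != T.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs T {T.shape}")
    contribution = R * T
    return contribution.sum(axis=0), contribution


def prepare_sites(seq: LocusSequence, pwms, threshold: float = 0.0,
                  mask: AccessibilityMask | None = None) -> list[BindingSite]:
    """Scan and mask once; the result can be passed to :func:`predict` to
    skip re-scanning when only parameters change (as during fitting)."""
    sites = scan_all(pwms, seq, threshold)
    return apply_mask(sites, mask, enabled=mask is not None)


def predict(seq: LocusSequence, pwms, params: ParameterSet,
            profiles: ProfileTable, mask: AccessibilityMask | None = None,
            mode: str = "competition", threshold: float = 0.0,
            context_cfg: ContextConfig = ContextConfig(),
            coop_max_gap: int = 60, sites=None) -> ModelOutput:
    """Full pipeline: scan -> mask -> weights -> occupancy -> context -> windows.

    ``mode="no_competition"`` treats the whole sequence as one window that
    always influences the promoter.  ``sites`` may carry the output of
    :func:`prepare_sites` to reuse a previous scan.
    """
    if mode not in ("competition", "no_competition"):
        raise ValueError(f"unknown mode {mode!r}")
    if sites is None:
        sites = prepare_sites(seq, pwms, threshold, mask)
    weights = site_weights(sites, params, profiles, pwms)

    coop = None
    for tf in params.tfs.values():
        if tf.cooperative and tf.omega > 1.0:
            coop = CooperativitySpec(tf.tf_name, tf.omega, coop_max_gap)
    occ = per_position_occupancy(sites, weights, coop)
    ea = effective_activation(occ, sites, params, context_cfg)

    g = params.globals_
    P = profiles.n_positions
    if mode == "no_competition":
        e_a = np.array([params.tfs[s.tf_name].E_A for s in sites])
        N_tot = (ea.F * e_a[:, None]).sum(axis=0) if sites else np.zeros(P)
        N = N_tot[None, :]
        R = window_rate(N, g.theta, g.Rmax)
        T = np.ones_like(N)
        R_total, contribution = locus_rate(R, T)
        starts = np.array([0])
    else:
        N = window_adaptors(ea, sites, params, g.alpha, seq.length)
        R = window_rate(N, g.theta, g.Rmax)
        T = window_time(N, g.beta)
        R_total, contribution = locus_rate(R, T)
        starts = window_starts(seq.length, g.alpha)

    return ModelOutput(R_total=R_total, mRNA_pred=R_total,
                       contribution_map=contribution, window_starts=starts,
                       N=N, R=R, T=T, mode=mode, sites=tuple(sites),
                       occupancy=occ, activation=ea)
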