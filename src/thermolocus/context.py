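"""Context-dependent TF action: coactivation, then short-range quenching.

Raw fractional occupancy f is first split into an activating part f_act and
a repressing part f_rep.  Pure activators activate with their whole
occupancy (f_act = f); pure repressors never activate (f_act = 0,
f_rep = f).  A coactivated repressor (the Hb-like case) switches to the
activating state in proportion to the chance that at least one coactivator
site within ``d_coact`` bp (centre-to-centre) is bound:

    f_act = f * E_C * (1 - prod_j (1 - f_j)),   f_rep = f - f_act,

the product running over coactivator sites j in range.  Quenching then
reduces each site's activating occupancy by every repressing site r within
``d_quench`` bp:

    F = f_act * prod_r (1 - E_Q(r) * f_rep_total(r)),

where f_rep_total is f for pure repressors and f_rep for coactivated ones.
Repressors do not quench other repressors, and a site never quenches
itself.  Coactivation is applied before quenching, without feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import OccupancyTable
from .params import ParameterSet


@dataclass(frozen=True)
class ContextConfig:
    d_coact: int = 150   # coactivation range, bp centre-to-centre
    d_quench: int = 100  # quenching range, bp centre-to-centre

    def __post_init__(self) -> None:
        if self.d_coact < 0 or self.d_quench < 0:
            raise ValueError("context distances must be >= 0")


@dataclass(frozen=True)
class EffectiveActivation:
    """Decomposition of occupancy into activating / repressing parts and the
    post-quenching effective activating strength F (all site x position)."""

    f_act: np.ndarray
    f_rep: np.ndarray
    F: np.ndarray | None = None


_LOG_FLOOR = 1e-300  # log of a fully saturating factor stays finite


def _range_log_products(member_mids, member_logs, query_mids, d):
    """For each query midpoint, the summed log terms of members within d.

    Members must carry one log term per axis position; the window
    |mid - query| <= d is resolved by prefix sums over mid-sorted members,
    so the whole sweep is O((m + q) log m) per position block.
    """
    order = np.argsort(member_mids, kind="stable")
    mids_sorted = member_mids[order]
    logs_sorted = member_logs[order]
    cum = np.vstack([np.zeros((1, logs_sorted.shape[1])),
                     np.cumsum(logs_sorted, axis=0)])
    lo = np.searchsorted(mids_sorted, query_mids - d, side="left")
    hi = np.searchsorted(mids_sorted, query_mids + d, side="right")
    return cum[hi] - cum[lo]


def coactivate(occ: OccupancyTable, sites, params: ParameterSet,
               cfg: ContextConfig = ContextConfig()) -> EffectiveActivation:
    """Fill f_act / f_rep from raw occupancy (F left for :func:`quench`)."""
    f = occ.f
    n, P = f.shape
    mids = np.array([s.midpoint for s in sites])
    tf_of = np.array([s.tf_name for s in sites])
    f_act = np.zeros((n, P))
    f_rep = np.zeros((n, P))

    for name, tf in params.tfs.items():
        idx = np.nonzero(tf_of == name)[0]
        if idx.size == 0:
            continue
        if tf.role == "activator":
            f_act[idx] = f[idx]
        elif tf.is_coactivated:
            co_idx = np.nonzero(np.isin(tf_of, tf.coactivated_by))[0]
            if co_idx.size:
                logs = np.log(np.maximum(1.0 - f[co_idx], _LOG_FLOOR))
                miss = _range_log_products(mids[co_idx], logs, mids[idx],
                                           cfg.d_coact)
                p_any = 1.0 - np.exp(miss)   # at least one coactivator bound
                f_act[idx] = f[idx] * tf.E_C * p_any
            f_rep[idx] = f[idx] - f_act[idx]
        else:
            f_rep[idx] = f[idx]
    return EffectiveActivation(f_act, f_rep)


def quench(ea: EffectiveActivation, sites, params: ParameterSet,
           cfg: ContextConfig = ContextConfig()) -> EffectiveActivation:
    """Fill F: activating occupancy scaled down by nearby repressing sites."""
    n, P = ea.f_act.shape
    mids = np.array([s.midpoint for s in sites])
    is_rep = np.array([params.tfs[s.tf_name].role == "repressor" for s in sites])
    rep_idx = np.nonzero(is_rep)[0]
    if rep_idx.size == 0 or n == 0:
        return EffectiveActivation(ea.f_act, ea.f_rep, ea.f_act.copy())

    e_q = np.array([params.tfs[sites[r].tf_name].E_Q for r in rep_idx])
    strength = e_q[:, None] * ea.f_rep[rep_idx]
    logs = np.log(np.maximum(1.0 - strength, _LOG_FLOOR))
    window = _range_log_products(mids[rep_idx], logs, mids, cfg.d_quench)
    # a repressing site never quenches itself
    self_pos = {int(r): i for i, r in enumerate(rep_idx)}
    for k, r in enumerate(rep_idx):
        window[r] -= logs[self_pos[int(r)]]
    F = ea.f_act * np.exp(window)
    return EffectiveActivation(ea.f_act, ea.f_rep, F)


def effective_activation(occ: OccupancyTable, sites, params: ParameterSet,
                         cfg: ContextConfig = ContextConfig()) -> EffectiveActivation:
    """Coactivation followed by quenching (the model's fixed order)."""
    return quench(coactivate(occ, sites, params, cfg), sites, params, cfg)
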