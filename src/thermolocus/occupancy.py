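"""Equilibrium fractional occupancy under steric exclusion and cooperativity.

A binding configuration is a subset of called sites whose footprints are
pairwise non-overlapping.  Its statistical weight is the product of the
member site weights q_i, times omega for every pair of *consecutively bound
sites of the cooperative TF* whose edge-to-edge gap is at most ``max_gap``
bp.  "Consecutive" means adjacent within the bound sites of the cooperative
TF; an intervening bound site of another TF does not break the pair.  The
fractional occupancy of site i is the weight share of configurations
containing i; the empty configuration has weight 1.

Two routes compute the same quantity:

* :func:`occupancy_bruteforce` — explicit enumeration of all 2^n subsets
  (guarded to n <= 20), the reference oracle;
* :func:`occupancy_dp` — a forward/backward dynamic program over sites
  sorted by start, linear in the number of sites for bounded local overlap.

The DP conditions on the identity of the most recently bound site (for
sterics, via a running prefix sum) and on the most recently bound
cooperative site (for the pairwise omega factor).  Cooperative states whose
footprint has fallen more than ``max_gap`` bp behind the scan frontier can
no longer contribute an omega factor and are folded into a single "distant"
state, which bounds the state space.  All accumulation is done in the log
domain, so weights as large as omega^n * prod q_i never overflow.

All routines are vectorised over axis positions: the configuration geometry
is shared across positions, only the weights differ.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .sites import SiteWeightMatrix

BRUTEFORCE_MAX_SITES = 20


@dataclass(frozen=True)
class CooperativitySpec:
    """Pairwise cooperativity for one TF: weight boost omega for nearest
    bound pairs of its sites within ``max_gap`` bp edge-to-edge."""

    tf_name: str
    omega: float
    max_gap: int = 60

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class OccupancyTable:
    """f[i, x] in [0, 1] per site and axis position; log partition per position."""

    f: np.ndarray      # (n_sites, n_positions)
    logZ: np.ndarray   # (n_positions,)


def _geometry(sites, coop: CooperativitySpec | None):
    starts = np.array([s.start for s in sites], dtype=np.int64)
    ends = np.array([s.end for s in sites], dtype=np.int64)
    if coop is not None and coop.omega > 1.0:
        is_coop = np.array([s.tf_name == coop.tf_name for s in sites], dtype=bool)
        log_omega = float(np.log(coop.omega))
        max_gap = coop.max_gap
    else:
        is_coop = np.zeros(len(sites), dtype=bool)
        log_omega = 0.0
        max_gap = 0
    return starts, ends, is_coop, log_omega, max_gap


def _log_weights(weights: SiteWeightMatrix) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(weights.q)


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle)
# ---------------------------------------------------------------------------

def occupancy_bruteforce(sites, weights: SiteWeightMatrix,
                         coop: CooperativitySpec | None = None) -> OccupancyTable:
    """Enumerate all 2^n binding configurations explicitly.

    Refuses n > 20.  Vectorised over subsets (bitmask arithmetic) and axis
    positions, so 200 instances at n = 15 run in seconds.
    """
    n = len(sites)
    if n > BRUTEFORCE_MAX_SITES:
        raise ValueError(f"brute force refuses n={n} > {BRUTEFORCE_MAX_SITES} sites")
    starts, ends, is_coop, log_omega, max_gap = _geometry(sites, coop)
    logq = _log_weights(weights)            # (n, P)
    P = logq.shape[1]
    if n == 0:
        return OccupancyTable(np.zeros((0, P)), np.zeros(P))

    masks = np.arange(1 << n, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(bool)   # (2^n, n)

    # steric validity: no overlapping pair may be jointly bound
    valid = np.ones(masks.size, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if starts[j] < ends[i] and starts[i] < ends[j]:
                pb = np.uint32((1 << i) | (1 << j))
                valid &= (masks & pb) != pb

    # cooperative pair count: coop pair (i, j) adjacent among bound coop sites
    coop_count = np.zeros(masks.size, dtype=np.int64)
    coop_idx = np.nonzero(is_coop)[0]
    for a, i in enumerate(coop_idx):
        for j in coop_idx[a + 1:]:
            if starts[j] - ends[i] > max_gap:
                continue
            pb = np.uint32((1 << int(i)) | (1 << int(j)))
            between = np.uint32(sum(1 << int(k) for k in coop_idx if i < k < j))
            hit = ((masks & pb) == pb)
            if between:
                hit &= (masks & between) == 0
            coop_count += hit

    # log weight per (subset, position); -1e30 sentinel keeps matmul NaN-free
    logq_safe = np.where(np.isneginf(logq), -1e30, logq)
    logW = bits.astype(float) @ logq_safe + (coop_count * log_omega)[:, None]
    logW[~valid] = -np.inf

    shift = logW.max(axis=0)
    W = np.exp(logW - shift)
    Zs = W.sum(axis=0)
    logZ = shift + np.log(Zs)
    f = (bits.astype(float).T @ W) / Zs
    return OccupancyTable(np.clip(f, 0.0, 1.0), logZ)


# ---------------------------------------------------------------------------
# dynamic program
# ---------------------------------------------------------------------------

def _forward(starts, ends, is_coop, logq, log_omega, max_gap):
    """One directional pass of the DP.

    Sites must be sorted by (start, end).  Returns ``(logZ, presums)`` where
    ``presums[j]`` maps a state key (a cooperative site index, or None for
    "no cooperative site within reach") to the log-sum of weights of
    configurations over sites before j that are compatible with binding j,
    conditioned on that most-recent-cooperative-site state.  Values are
    vectors over axis positions.
    """
    n = len(starts)
    P = logq.shape[1]
    NEG = np.full(P, -np.inf)

    cum: dict = {None: np.zeros(P)}      # log 1: the empty prefix
    open_heap: list = []                 # (end_i, i, F_i dict)
    presums: list[dict] = [None] * n
    total = np.zeros(P)                  # log Z accumulates 1 + sum_j sum_c F[j][c]

    def fold_key(d, key, frontier):
        """Merge state ``key`` into None if its site can no longer interact."""
        if key is None:
            return
        if ends[key] < frontier - max_gap:
            v = d.pop(key)
            d[None] = np.logaddexp(d.get(None, NEG), v)

    for j in range(n):
        sj = starts[j]
        # close finished sites into the running prefix sum
        while open_heap and open_heap[0][0] <= sj:
            _, _, Fi = heapq.heappop(open_heap)
            for key, v in Fi.items():
                if key is not None and ends[key] < sj - max_gap:
                    key = None
                cum[key] = np.logaddexp(cum.get(key, NEG), v)
        # fold stale cooperative states
        for key in [k for k in cum if k is not None and ends[k] < sj - max_gap]:
            fold_key(cum, key, sj)

        presums[j] = dict(cum)

        if is_coop[j]:
            # every surviving non-None state is within max_gap => factor omega
            acc = NEG
            for key, v in cum.items():
                acc = np.logaddexp(acc, v if key is None else v + log_omega)
            Fj = {j: acc + logq[j]}
        else:
            Fj = {key: v + logq[j] for key, v in cum.items()}

        for v in Fj.values():
            total = np.logaddexp(total, v)
        heapq.heappush(open_heap, (ends[j], j, Fj))

    return total, presums


def occupancy_dp(sites, weights: SiteWeightMatrix,
                 coop: CooperativitySpec | None = None) -> OccupancyTable:
    """Forward/backward DP; matches :func:`occupancy_bruteforce` exactly
    (to floating-point accumulation error) on any input the oracle accepts."""
    n = len(sites)
    starts, ends, is_coop, log_omega, max_gap = _geometry(sites, coop)
    logq = _log_weights(weights)
    P = logq.shape[1]
    if n == 0:
        return OccupancyTable(np.zeros((0, P)), np.zeros(P))

    order_f = sorted(range(n), key=lambda i: (starts[i], ends[i], i))
    logZ_f, pre_f = _forward(starts[order_f], ends[order_f], is_coop[order_f],
                             logq[order_f], log_omega, max_gap)

    # mirrored pass: suffix sums become prefix sums of the reflected locus
    m_starts, m_ends = -ends, -starts
    order_b = sorted(range(n), key=lambda i: (m_starts[i], m_ends[i], i))
    logZ_b, pre_b = _forward(m_starts[order_b], m_ends[order_b], is_coop[order_b],
                             logq[order_b], log_omega, max_gap)

    pos_f = {orig: k for k, orig in enumerate(order_f)}
    pos_b = {orig: k for k, orig in enumerate(order_b)}

    f = np.empty((n, P))
    for j in range(n):
        PSf = pre_f[pos_f[j]]
        PSb = pre_b[pos_b[j]]
        acc = np.full(P, -np.inf)
        for cf_local, vf in PSf.items():
            c = None if cf_local is None else order_f[cf_local]
            for cb_local, vb in PSb.items():
                ct = None if cb_local is None else order_b[cb_local]
                if is_coop[j]:
                    # folding guarantees surviving states are within max_gap of j
                    x = (log_omega if c is not None else 0.0) + \
                        (log_omega if ct is not None else 0.0)
                else:
                    # prefix and suffix cooperative sites may pair across j
                    x = log_omega if (c is not None and ct is not None and
                                      starts[ct] - ends[c] <= max_gap) else 0.0
                acc = np.logaddexp(acc, vf + vb + x)
        f[j] = np.exp(acc + logq[j] - logZ_f)

    return OccupancyTable(np.clip(f, 0.0, 1.0), logZ_f)


def per_position_occupancy(sites, weights: SiteWeightMatrix,
                           coop: CooperativitySpec | None = None) -> OccupancyTable:
    """Occupancy at every axis position.

    The DP already runs all positions in one sweep (the configuration
    geometry is position-independent), so this simply delegates; column x of
    the result equals :func:`occupancy_dp` on weight column x alone.
    """
    return occupancy_dp(sites, weights, coop)
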