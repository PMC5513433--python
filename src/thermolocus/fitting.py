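"""Parameter estimation: SSE objective, adaptive simulated annealing, and
the two optimisation controls (fit-known-optimum, permuted-sequence).

The annealer works in a transformed unit cube: each free parameter is
mapped to [0, 1] linearly, or logarithmically for parameters whose search
range spans several decades (A, omega, beta, Rmax).  Proposals are
per-coordinate Gaussian steps reflected at the bounds; step sizes adapt
toward a moderate acceptance rate; the temperature follows a geometric
schedule whose length scales as 1/kappa (smaller kappa = more accurate,
slower).  An optional deterministic L-BFGS-B polish refines the best state
found.  Everything is driven by an integer seed and is exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .competition import predict, prepare_sites
from .io import AccessibilityMask, LocusSequence, ProfileTable
from .params import ParameterSet
from .synthetic import ProblemBundle


@dataclass(frozen=True)
class AnnealConfig:
    """kappa is the accuracy knob: the move budget defaults to ~30/kappa."""

    kappa: float = 0.05
    seed: int = 0
    max_moves: int | None = None
    restarts: int = 1
    polish: bool = True
    trace_every: int = 25

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def moves(self) -> int:
        return self.max_moves if self.max_moves is not None else int(30.0 / self.kappa)


@dataclass
class FitResult:
    best_params: ParameterSet | None
    sse: float
    trace: list[tuple[int, float]]
    seed: int
    best_x: np.ndarray | None = None
    n_evals: int = 0


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def sse_objective(params: ParameterSet, seq: LocusSequence, pwms,
                  profiles: ProfileTable, target: np.ndarray,
                  mode: str = "competition",
                  mask: AccessibilityMask | None = None,
                  threshold: float = 0.0, sites=None) -> float:
    """Sum of squared differences between predicted and observed mRNA."""
    target = np.asarray(target, dtype=float)
    if target.size != profiles.n_positions:
        raise ValueError("target length does not match number of axis positions")
    out = predict(seq, pwms, params, profiles, mask=mask, mode=mode,
                  threshold=threshold, sites=sites)
    return float(np.sum((out.mRNA_pred - target) ** 2))


# ---------------------------------------------------------------------------
# annealer (transformed-coordinate adaptive SA)
# ---------------------------------------------------------------------------

class _Transform:
    def __init__(self, bounds, log_scale):
        self.lo = np.array([b[0] for b in bounds], dtype=float)
        self.hi = np.array([b[1] for b in bounds], dtype=float)
        self.log = np.asarray(log_scale, dtype=bool)
        if np.any(self.log & (self.lo <= 0)):
            raise ValueError("log-scale parameter with non-positive lower bound")

    def to_unit(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(all="ignore"):  # unused np.where branch may log(0)
            t = np.where(self.log,
                         (np.log(np.maximum(x, 1e-300)) - np.log(np.maximum(self.lo, 1e-300)))
                         / (np.log(self.hi) - np.log(np.maximum(self.lo, 1e-300))),
                         (x - self.lo) / (self.hi - self.lo))
        return np.clip(t, 0.0, 1.0)

    def from_unit(self, t):
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        with np.errstate(all="ignore"):
            lo_safe = np.maximum(self.lo, 1e-300)
            x = np.where(self.log,
                         np.exp(np.log(lo_safe) + t * (np.log(self.hi) - np.log(lo_safe))),
                         self.lo + t * (self.hi - self.lo))
        # guard round-off past the bounds
        return np.minimum(np.maximum(x, self.lo), self.hi)


def _reflect(t: float) -> float:
    # reflect into [0, 1] (handles any finite excursion)
    t = math.fmod(t, 2.0)
    if t < 0:
        t += 2.0
    return 2.0 - t if t > 1.0 else t


def anneal(objective, bounds, cfg: AnnealConfig, log_scale=None,
           x0=None) -> FitResult:
    """Minimise ``objective(x)`` within ``bounds``.

    Returns a :class:`FitResult` whose ``best_x`` is the best parameter
    vector seen (after optional polish) and whose trace logs (move, sse)
    pairs.  Two runs with the same config and seed are identical.
    """
    d = len(bounds)
    log_scale = [False] * d if log_scale is None else list(log_scale)
    tr = _Transform(bounds, log_scale)
    rng = np.random.default_rng(cfg.seed)
    n_evals = 0

    def f(t):
        nonlocal n_evals
        n_evals += 1
        return float(objective(tr.from_unit(t)))

    t = tr.to_unit(x0) if x0 is not None else rng.random(d)
    e = f(t)
    best_t, best_e = t.copy(), e
    trace: list[tuple[int, float]] = [(0, e)]

    # temperature scale from an initial random walk
    deltas = []
    probe = t.copy()
    for _ in range(max(10, 2 * d)):
        k = rng.integers(d)
        cand = probe.copy()
        cand[k] = _reflect(cand[k] + rng.normal(0.0, 0.25))
        e2 = f(cand)
        deltas.append(abs(e2 - e))
        probe = cand
        if e2 < best_e:
            best_t, best_e = cand.copy(), e2
    T0 = max(float(np.median(deltas)), 1e-12)
    Tf = T0 * 1e-8

    sigma = np.full(d, 0.25)
    accepted = np.zeros(d)
    tried = np.zeros(d)
    moves = max(cfg.moves, 1)
    for m in range(1, moves + 1):
        T = T0 * (Tf / T0) ** (m / moves)
        k = int(rng.integers(d))
        cand = t.copy()
        cand[k] = _reflect(cand[k] + rng.normal(0.0, sigma[k]))
        e2 = f(cand)
        tried[k] += 1
        if e2 <= e or rng.random() < math.exp(-(e2 - e) / T):
            t, e = cand, e2
            accepted[k] += 1
            if e < best_e:
                best_t, best_e = t.copy(), e
        if tried[k] >= 20:
            rate = accepted[k] / tried[k]
            if rate > 0.6:
                sigma[k] = min(sigma[k] * 1.4, 0.5)
            elif rate < 0.2:
                sigma[k] = max(sigma[k] * 0.7, 1e-4)
            accepted[k] = tried[k] = 0
        if m % cfg.trace_every == 0 or m == moves:
            trace.append((m, e))

    if cfg.polish:
        # gradient polish, then a derivative-free pass to escape the noise
        # floor of finite-difference gradients near the optimum
        res = optimize.minimize(f, best_t, method="L-BFGS-B",
                                bounds=[(0.0, 1.0)] * d,
                                options={"maxiter": 500, "ftol": 1e-16,
                                         "gtol": 1e-12})
        if res.fun < best_e:
            best_t, best_e = np.clip(res.x, 0.0, 1.0), float(res.fun)
        res2 = optimize.minimize(f, best_t, method="Nelder-Mead",
                                 bounds=[(0.0, 1.0)] * d,
                                 options={"maxfev": 120 * d, "xatol": 1e-9,
                                          "fatol": 1e-12})
        if res2.fun < best_e:
            best_t, best_e = np.clip(res2.x, 0.0, 1.0), float(res2.fun)
        trace.append((moves + int(res.nfev) + int(res2.nfev), best_e))

    return FitResult(best_params=None, sse=best_e, trace=trace, seed=cfg.seed,
                     best_x=tr.from_unit(best_t), n_evals=n_evals)


# ---------------------------------------------------------------------------
# model-level fitting
# ---------------------------------------------------------------------------

def fit_locus(template: ParameterSet, problem: ProblemBundle,
              target: np.ndarray, cfg: AnnealConfig,
              mask: AccessibilityMask | None = None) -> FitResult:
    """Fit the template's free parameters to a target profile; best of
    ``cfg.restarts`` independently seeded runs, each from a random start."""
    if not template.free:
        raise ValueError("template has no free parameters")
    bounds = [template.bounds_of(n) for n in template.free]
    log_scale = [template.log_scale_of(n) for n in template.free]
    sites = prepare_sites(problem.seq, problem.pwms, problem.threshold, mask)

    def objective(x):
        ps = template.with_vector(x)
        return sse_objective(ps, problem.seq, problem.pwms, problem.profiles,
                             target, mode=problem.mode, mask=mask,
                             threshold=problem.threshold, sites=sites)

    best: FitResult | None = None
    for r in range(cfg.restarts):
        sub = AnnealConfig(cfg.kappa, int(np.random.default_rng([cfg.seed, r]).integers(2**31)),
                           cfg.max_moves, 1, cfg.polish, cfg.trace_every)
        x0 = template.sample_free(np.random.default_rng([cfg.seed, r, 7])).to_vector()
        res = anneal(objective, bounds, sub, log_scale, x0=x0)
        if best is None or res.sse < best.sse:
            best = res
    best.best_params = template.with_vector(best.best_x, provenance="fitted")
    return best


def fit_known_optimum_control(true_params: ParameterSet, cfg: AnnealConfig,
                              problem: ProblemBundle,
                              mask: AccessibilityMask | None = None
                              ) -> tuple[FitResult, float]:
    """Refit against the model's own output, where the global minimum is a
    known zero; returns the fit and the Spearman rank correlation between
    the true and recovered free-parameter vectors."""
    if not true_params.free:
        raise ValueError("true_params must declare free parameters")
    out = predict(problem.seq, problem.pwms, true_params, problem.profiles,
                  mask=mask, mode=problem.mode, threshold=problem.threshold)
    result = fit_locus(true_params, problem, out.mRNA_pred, cfg, mask=mask)
    rho = float(stats.spearmanr(true_params.to_vector(), result.best_x).statistic)
    return result, rho


def permute_sequence(seq: LocusSequence, rng: np.random.Generator,
                     protected=()) -> LocusSequence:
    """Shuffle the bases outside ``protected`` intervals (multiset preserved)."""
    bases = np.array(list(seq.bases))
    keep = np.zeros(seq.length, dtype=bool)
    for s, e in protected:
        keep[s:e] = True
    idx = np.nonzero(~keep)[0]
    bases[idx] = bases[rng.permutation(idx)]
    return LocusSequence(seq.name + "_permuted", "".join(bases))


def permutation_control(template: ParameterSet, problem: ProblemBundle,
                        target: np.ndarray, cfg: AnnealConfig,
                        n_permutations: int = 3, protected=(),
                        mask: AccessibilityMask | None = None) -> list[FitResult]:
    """Best fit to each of ``n_permutations`` shuffled-sequence variants of
    the problem, for comparison against the real-sequence fit."""
    results = []
    for p in range(n_permutations):
        rng = np.random.default_rng([cfg.seed, 1000 + p])
        pseq = permute_sequence(problem.seq, rng, protected)
        pprob = ProblemBundle(pseq, problem.pwms, problem.profiles,
                              (), problem.mode, problem.threshold)
        sub = AnnealConfig(cfg.kappa, cfg.seed + 31 * (p + 1), cfg.max_moves,
                           cfg.restarts, cfg.polish, cfg.trace_every)
        results.append(fit_locus(template, pprob, target, sub, mask=mask))
    return results
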