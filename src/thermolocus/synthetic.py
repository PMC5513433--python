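"""Self-contained synthetic fixtures: toy PWMs, loci with planted sites,
gap-gene-like concentration profiles, and known-optimum fitting problems.

Everything is generated from an integer seed through independent
``numpy.random.default_rng`` streams, so outputs are byte-identical across
runs and platforms and no download is ever required.

The standing end-to-end fixture is :func:`benchmark`: a 6 kb locus carrying
two planted enhancers ~3 kb apart, six TFs (a cooperative anterior-gradient
activator, a uniform activator, two bump repressors, a posterior-gradient
repressor, and a coactivated repressor with an anterior-plus-band profile)
and 58 axis positions spanning 35.5-92.5 % embryo length.  With the
hand-chosen parameters of :func:`benchmark_params` it drives two separated
expression domains under competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LocusSequence, ProfileTable, PWMRecord, BASE_ORDER
from .params import GlobalParameters, ParameterSet, TFParameters

_COMPLEMENT_STR = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TFRoster:
    """One synthetic TF: identity, regulatory role and profile shape.

    ``profile_shape`` is one of ``("anterior_gradient", tau)``,
    ``("posterior_gradient", tau)``, ``("bump", center, width)``,
    ``("uniform", level)``, ``("two_domain",)``; amplitudes are scaled by
    ``level`` (0-1) of the spec-wide fluorescence ceiling.
    """

    name: str
    role: str
    profile_shape: tuple
    coactivated_by: tuple[str, ...] = ()
    pwm_length: int = 10
    information_content: float = 0.9
    level: float = 1.0
    cooperative: bool = False


@dataclass(frozen=True)
class PlantedSite:
    tf_name: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class EnhancerPlan:
    """A planted enhancer: (tf_name, offset[, strand]) site plan at ``start``."""

    name: str
    start: int
    sites: tuple = ()


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    locus_length: int = 6000
    tf_roster: tuple[TFRoster, ...] = ()
    enhancers: tuple[EnhancerPlan, ...] = ()
    n_positions: int = 58
    position_start: float = 35.5
    position_step: float = 1.0
    gc: float = 0.41
    amplitude: float = 255.0
    allow_overlap: bool = False


@dataclass(frozen=True)
class ProblemBundle:
    """Everything needed to evaluate the model on a synthetic problem."""

    seq: LocusSequence
    pwms: tuple[PWMRecord, ...]
    profiles: ProfileTable
    truth: tuple[PlantedSite, ...] = ()
    mode: str = "competition"
    threshold: float = 0.0


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_toy_pwms(spec: SyntheticSpec) -> list[PWMRecord]:
    """Distinct-consensus count PWMs with controlled information content."""
    names = [tf.name for tf in spec.tf_roster]
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names in roster")
    rng = _rng(spec, 1)
    used: set[str] = set()
    pwms = []
    for tf in spec.tf_roster:
        if tf.pwm_length < 4:
            raise ValueError("pwm_length must be >= 4")
        while True:
            consensus = "".join(BASE_ORDER[i] for i in rng.integers(0, 4, tf.pwm_length))
            if consensus not in used:
                used.add(consensus)
                break
        p_hit = 0.25 + 0.75 * tf.information_content
        counts = np.full((tf.pwm_length, 4), round(1000 * (1 - p_hit) / 3))
        for j, base in enumerate(consensus):
            counts[j, BASE_ORDER.index(base)] = round(1000 * p_hit)
        pwms.append(PWMRecord.from_counts(tf.name, counts, pseudocount=1.0))
    return pwms


def consensus_of(pwm: PWMRecord) -> str:
    return "".join(BASE_ORDER[j] for j in pwm.matrix.argmax(axis=1))


def make_locus(spec: SyntheticSpec, pwms) -> tuple[LocusSequence, list[PlantedSite]]:
    """I.i.d. background at the stated GC fraction with planted consensus sites."""
    rng = _rng(spec, 2)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    bases = list(BASE_ORDER[i] for i in rng.choice(4, size=spec.locus_length, p=p))
    by_name = {pwm.tf_name: pwm for pwm in pwms}

    truth: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for enh in spec.enhancers:
        for plan in enh.sites:
            tf_name, offset = plan[0], plan[1]
            strand = plan[2] if len(plan) > 2 else "+"
            mismatches = plan[3] if len(plan) > 3 else 0
            word = consensus_of(by_name[tf_name])
            if mismatches:
                # deterministic controlled-mismatch variant: substitute the
                # next base cyclically at evenly spaced positions
                chars = list(word)
                step = max(1, len(chars) // mismatches)
                changed = 0
                for j in range(0, len(chars), step):
                    if changed >= mismatches:
                        break
                    chars[j] = BASE_ORDER[(BASE_ORDER.index(chars[j]) + 1) % 4]
                    changed += 1
                word = "".join(chars)
            if strand == "-":
                word = word.translate(_COMPLEMENT_STR)[::-1]
            start = enh.start + offset
            end = start + len(word)
            if not (0 <= start < end <= spec.locus_length):
                raise ValueError(f"planted site {tf_name}@{start} outside locus")
            if not spec.allow_overlap:
                for s, e in occupied:
                    if start < e and s < end:
                        raise ValueError(f"planted sites overlap at {start}")
            occupied.append((start, end))
            bases[start:end] = list(word)
            truth.append(PlantedSite(tf_name, start, end, strand))
    return LocusSequence(f"synthetic_locus_seed{spec.seed}", "".join(bases)), truth


def _shape_curve(shape: tuple, x: np.ndarray, amplitude: float) -> np.ndarray:
    kind = shape[0]
    lo, hi = x[0], x[-1] if x.size > 1 else x[0] + 1.0
    if kind == "anterior_gradient":
        tau = shape[1] if len(shape) > 1 else 15.0
        return amplitude * np.exp(-(x - lo) / tau)
    if kind == "posterior_gradient":
        tau = shape[1] if len(shape) > 1 else 15.0
        return amplitude * np.exp(-(hi - x) / tau)
    if kind == "bump":
        center, width = shape[1], shape[2]
        return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width ** 2))
    if kind == "uniform":
        return np.full_like(x, amplitude)
    if kind == "two_domain":
        # anterior plateau plus a posterior band (Hb-like)
        plateau = 1.0 / (1.0 + np.exp((x - 47.0) / 2.5))
        band = 0.65 * np.exp(-((x - 78.0) ** 2) / (2.0 * 4.0 ** 2))
        return amplitude * (0.9 * plateau + band)
    raise ValueError(f"unknown profile shape {kind!r}")


def make_profiles(spec: SyntheticSpec) -> ProfileTable:
    """Smooth non-negative concentration curves on the shared axis grid."""
    x = spec.position_start + spec.position_step * np.arange(spec.n_positions)
    cols = {
        tf.name: _shape_curve(tf.profile_shape, x, spec.amplitude * tf.level)
        for tf in spec.tf_roster
    }
    return ProfileTable(x, cols)


def make_parameter_set(spec: SyntheticSpec, overrides: dict | None = None,
                       globals_: GlobalParameters | None = None,
                       free: tuple[str, ...] = ()) -> ParameterSet:
    """ParameterSet skeleton for the roster; ``overrides`` maps
    ``tf_name -> field dict`` onto the defaults."""
    overrides = overrides or {}
    tfs = {}
    for tf in spec.tf_roster:
        kw = dict(tf_name=tf.name, role=tf.role,
                  coactivated_by=tf.coactivated_by, cooperative=tf.cooperative)
        kw.update(overrides.get(tf.name, {}))
        tfs[tf.name] = TFParameters(**kw)
    return ParameterSet(tfs, globals_ or GlobalParameters(), free)


def make_problem(spec: SyntheticSpec, mode: str = "competition",
                 threshold: float = 0.0) -> ProblemBundle:
    pwms = make_toy_pwms(spec)
    seq, truth = make_locus(spec, pwms)
    profiles = make_profiles(spec)
    return ProblemBundle(seq, tuple(pwms), profiles, tuple(truth), mode, threshold)


def make_known_optimum_problem(spec: SyntheticSpec, params: ParameterSet,
                               mode: str = "competition",
                               threshold: float = 0.0):
    """Problem whose target is the model's own output: known SSE minimum 0."""
    from .competition import predict  # deferred: competition imports params too

    bundle = make_problem(spec, mode, threshold)
    out = predict(bundle.seq, bundle.pwms, params, bundle.profiles,
                  mode=mode, threshold=threshold)
    return bundle, out.mRNA_pred.copy()


# ---------------------------------------------------------------------------
# the standing two-enhancer benchmark
# ---------------------------------------------------------------------------

BENCHMARK_ROSTER = (
    TFRoster("Bia", "activator", ("anterior_gradient", 15.0), cooperative=True),
    TFRoster("Uni", "activator", ("uniform", 1.0), level=0.5),
    TFRoster("Rga", "repressor", ("bump", 52.0, 3.0)),
    TFRoster("Rgb", "repressor", ("bump", 50.0, 8.0)),
    TFRoster("Rter", "repressor", ("posterior_gradient", 5.0)),
    TFRoster("Hbl", "repressor", ("two_domain",), coactivated_by=("Bia", "Uni")),
)

# stripeA: cooperative Bia pair + Uni, bordered by Rga (posterior edge) and
# Rter (posterior suppression).  stripeB: Uni sites plus coactivated Hbl,
# bordered by the wide Rgb bump (anterior) and Rter (posterior).
BENCHMARK_ENHANCERS = (
    EnhancerPlan("stripeA", 1000, (
        ("Rter", 0), ("Bia", 20), ("Bia", 50, "-"), ("Rga", 75), ("Rter", 100),
    )),
    EnhancerPlan("stripeB", 4000, (
        ("Rgb", 0), ("Uni", 25), ("Hbl", 50), ("Uni", 95, "-"),
        ("Hbl", 120), ("Rter", 150), ("Rgb", 175),
    )),
)


def benchmark_spec(seed: int = 0, locus_length: int = 6000) -> SyntheticSpec:
    return SyntheticSpec(seed=seed, locus_length=locus_length,
                         tf_roster=BENCHMARK_ROSTER,
                         enhancers=BENCHMARK_ENHANCERS)


#: free parameters used by the scaled-down parameter-recovery control
BENCHMARK_FREE = ("Bia.A", "Uni.A", "Bia.E_A", "Uni.E_A", "Rga.E_Q",
                  "Rter.E_Q", "Hbl.E_C", "theta", "beta", "Rmax")


def benchmark_params(free: tuple[str, ...] = ()) -> ParameterSet:
    """Hand-chosen parameters that drive two separated stripes."""
    tfs = {
        "Bia": TFParameters("Bia", "activator", A=0.002, lam=1.0, E_A=8.0,
                            cooperative=True, omega=50.0),
        "Uni": TFParameters("Uni", "activator", A=0.02, lam=1.0, E_A=6.0),
        "Rga": TFParameters("Rga", "repressor", A=0.1, lam=1.0, E_Q=0.9),
        "Rgb": TFParameters("Rgb", "repressor", A=0.1, lam=1.0, E_Q=0.9),
        "Rter": TFParameters("Rter", "repressor", A=0.05, lam=1.0, E_Q=0.85),
        "Hbl": TFParameters("Hbl", "repressor", A=0.05, lam=1.0, E_A=7.0,
                            E_Q=0.9, E_C=0.8, coactivated_by=("Bia", "Uni")),
    }
    glb = GlobalParameters(theta=10.0, beta=0.005, Rmax=240.0, alpha=1000)
    return ParameterSet(tfs, glb, tuple(free))


def benchmark(seed: int = 0) -> tuple[SyntheticSpec, ProblemBundle, ParameterSet]:
    spec = benchmark_spec(seed)
    return spec, make_problem(spec), benchmark_params()
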