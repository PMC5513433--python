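import numpy as np
import pytest
from dataclasses import replace

from thermolocus import (ContextConfig, GlobalParameters, ParameterSet,
                         TFParameters, locus_rate, n_windows, predict,
                         window_adaptors, window_rate, window_time)
from thermolocus.context import EffectiveActivation
from thermolocus.io import LocusSequence, ProfileTable, PWMRecord
from thermolocus.occupancy import occupancy_bruteforce
from thermolocus.params import ParameterSet as PS
from thermolocus.sites import BindingSite, SiteWeightMatrix, scan_all, site_weights


def one_site_ea(F_value, mid_start, locus_length, n_pos=1, E_A=1.0):
    sites = [BindingSite(0, "A", mid_start, mid_start + 8, "+", 1.0)]
    F = np.full((1, n_pos), F_value)
    params = ParameterSet({"A": TFParameters("A", "activator", E_A=E_A)},
                          GlobalParameters())
    ea = EffectiveActivation(f_act=F, f_rep=np.zeros_like(F), F=F)
    return ea, sites, params


# --- window bookkeeping -----------------------------------------------------

def test_window_count_is_l_plus_alpha():
    for l, alpha in ((100, 50), (6000, 1000), (13150, 1000)):
        assert n_windows(l, alpha) == l + alpha


def test_no_activating_sites_gives_zero_N():
    ea, sites, params = one_site_ea(0.5, 50, 200)
    params = ParameterSet({"A": TFParameters("A", "activator", E_A=0.0)},
                          GlobalParameters())
    N = window_adaptors(ea, sites, params, alpha=30, locus_length=200)
    assert np.all(N == 0.0)


def test_single_site_occupies_exactly_alpha_windows():
    alpha = 37
    ea, sites, params = one_site_ea(1.0, 100, 300, E_A=3.0)
    N = window_adaptors(ea, sites, params, alpha=alpha, locus_length=300)
    covered = np.nonzero(N[:, 0])[0]
    assert covered.size == alpha
    assert np.all(N[covered, 0] == pytest.approx(3.0))
    # contiguous run of windows whose interval covers the midpoint
    assert np.array_equal(covered, np.arange(covered[0], covered[0] + alpha))


def test_alpha_spanning_locus_reduces_to_total_sum():
    ea, sites, params = one_site_ea(0.6, 10, 50, E_A=5.0)
    N = window_adaptors(ea, sites, params, alpha=50, locus_length=50)
    assert N.max() == pytest.approx(0.6 * 5.0)


# --- rate and time laws -----------------------------------------------------

def test_rate_law_midpoint_and_saturation():
    assert window_rate(np.array([[10.0]]), 10.0, 200.0)[0, 0] == pytest.approx(100.0)
    assert window_rate(np.array([[1e3]]), 10.0, 200.0)[0, 0] == pytest.approx(200.0)
    # basal leak at theta = 25 with no activation
    leak = window_rate(np.array([[0.0]]), 25.0, 1.0)[0, 0]
    assert leak == pytest.approx(1.0 / (1.0 + np.exp(25.0)), rel=1e-12)
    assert leak == pytest.approx(1.388e-11, rel=1e-3)


def test_time_fraction_identities():
    N = np.array([[1.0], [1.0]])
    T = window_time(N, beta=1.0)
    assert np.allclose(T, 1.0 / 3.0)            # beta N / (1 + 2 beta N)
    assert window_time(np.zeros((4, 2)), 2.0).sum() == 0.0

    rng = np.random.default_rng(0)
    N = rng.uniform(0, 5, size=(40, 6))
    for beta in (1e-3, 0.3, 10.0):
        T = window_time(N, beta)
        S = beta * N.sum(axis=0)
        assert np.allclose(T.sum(axis=0), S / (1 + S), atol=1e-12)
        assert np.all(T.sum(axis=0) < 1.0)
    # large-beta limit: relative weighting N_m / sum N
    T_inf = window_time(N, 1e9)
    assert np.allclose(T_inf, N / N.sum(axis=0, keepdims=True), atol=1e-8)


def test_locus_rate_identities():
    R = np.array([[5.0], [0.0]])
    T = np.array([[0.25], [0.3]])
    total, cmap = locus_rate(R, T)
    assert total[0] == pytest.approx(1.25)       # single nonzero window
    assert cmap[0, 0] == pytest.approx(1.25)
    with pytest.raises(ValueError):
        locus_rate(R, T[:1])

    rng = np.random.default_rng(1)
    Rr = rng.uniform(0, 9, (30, 4))
    Tr = window_time(rng.uniform(0, 2, (30, 4)), 0.1)
    tot, _ = locus_rate(Rr, Tr)
    assert np.all(tot <= Rr.max(axis=0))         # convexity: sum T < 1


# --- end-to-end oracle on a hand-built locus --------------------------------

def test_small_locus_matches_independent_recomputation():
    """A 200 bp locus with 3 planted sites, recomputed from scratch with
    explicit window loops and brute-force occupancy."""
    pwm = PWMRecord.from_counts("A", np.array(
        [[90, 3, 3, 4], [3, 90, 4, 3], [3, 4, 90, 3], [4, 3, 3, 90],
         [90, 3, 3, 4], [3, 90, 4, 3]]))
    rng = np.random.default_rng(21)
    bases = list("ACGT"[i] for i in rng.integers(0, 4, 200))
    for start in (40, 80, 150):
        bases[start:start + 6] = list("ACGTAC")
    seq = LocusSequence("toy", "".join(bases))
    profiles = ProfileTable(np.array([50.0, 60.0]),
                            {"A": np.array([40.0, 200.0])})
    params = ParameterSet({"A": TFParameters("A", "activator", A=0.01,
                                             lam=1.2, E_A=4.0)},
                          GlobalParameters(theta=6.0, beta=0.02, Rmax=100.0,
                                           alpha=60))
    out = predict(seq, [pwm], params, profiles, threshold=5.0)

    # --- independent recomputation ------------------------------------
    sites = scan_all([pwm], seq, 5.0)
    w = site_weights(sites, params, profiles, [pwm])
    occ = occupancy_bruteforce(sites, w, None)   # exhaustive enumeration
    F = occ.f                                    # single pure activator: F = f
    alpha, l = 60, 200
    for x in range(2):
        contributions = []
        for m in range(-alpha, l):               # every window start
            N_m = sum(F[k, x] * 4.0 for k, s in enumerate(sites)
                      if m <= (s.start + s.end) / 2 < m + alpha)
            contributions.append(N_m)
        N_m = np.array(contributions)
        R_m = 100.0 / (1.0 + np.exp(6.0 - N_m))
        S = 0.02 * N_m.sum()
        T_m = 0.02 * N_m / (1.0 + S)
        expected = float((R_m * T_m).sum())
        assert out.R_total[x] == pytest.approx(expected, rel=1e-9)


# --- predict modes ----------------------------------------------------------

def test_no_competition_single_window_relation(bench):
    _, bundle, params = bench
    frag = bundle.seq.subsequence(900, 1300)     # length <= alpha
    comp = predict(frag, bundle.pwms, params, bundle.profiles, mode="competition")
    nocomp = predict(frag, bundle.pwms, params, bundle.profiles,
                     mode="no_competition")
    # the no-competition N equals the fullest competition window
    assert np.allclose(nocomp.N[0], comp.N.max(axis=0), atol=1e-12)
    # and its rate is not T-weighted
    g = params.globals_
    assert np.allclose(nocomp.R_total,
                       g.Rmax / (1 + np.exp(g.theta - nocomp.N[0])))


def test_all_zero_concentrations_basal_output(bench):
    _, bundle, params = bench
    zeroed = ProfileTable(bundle.profiles.positions,
                          {k: np.zeros_like(v)
                           for k, v in bundle.profiles.columns.items()})
    comp = predict(bundle.seq, bundle.pwms, params, zeroed)
    assert np.allclose(comp.R_total, 0.0)        # no engaged windows
    nocomp = predict(bundle.seq, bundle.pwms, params, zeroed,
                     mode="no_competition")
    g = params.globals_
    assert np.allclose(nocomp.R_total, g.Rmax / (1 + np.exp(g.theta)))


def test_unknown_mode_rejected(bench):
    _, bundle, params = bench
    with pytest.raises(ValueError):
        predict(bundle.seq, bundle.pwms, params, bundle.profiles, mode="other")


# --- competition consequences on the benchmark ------------------------------

def test_two_enhancers_are_subadditive(bench, bench_output):
    _, bundle, params = bench
    outA = predict(bundle.seq.subsequence(800, 1400), bundle.pwms, params,
                   bundle.profiles)
    outB = predict(bundle.seq.subsequence(3800, 4400), bundle.pwms, params,
                   bundle.profiles)
    combined = bench_output.mRNA_pred
    separate = outA.mRNA_pred + outB.mRNA_pred
    assert np.all(combined < separate)
    # and each fragment really drives output on its own
    assert outA.mRNA_pred.max() > 10.0 and outB.mRNA_pred.max() > 10.0


def test_output_robust_to_halving_alpha(bench, bench_output):
    _, bundle, params = bench
    p500 = PS(params.tfs, replace(params.globals_, alpha=500), params.free)
    out500 = predict(bundle.seq, bundle.pwms, p500, bundle.profiles)
    corr = np.corrcoef(bench_output.mRNA_pred, out500.mRNA_pred)[0, 1]
    assert corr >= 0.95


def test_R_total_monotone_in_beta(bench):
    _, bundle, params = bench
    outputs = []
    for beta in (1e-3, 5e-3, 2e-2):
        p = PS(params.tfs, replace(params.globals_, beta=beta), params.free)
        outputs.append(predict(bundle.seq, bundle.pwms, p,
                               bundle.profiles).R_total)
    assert np.all(outputs[1] >= outputs[0] - 1e-9)
    assert np.all(outputs[2] >= outputs[1] - 1e-9)
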