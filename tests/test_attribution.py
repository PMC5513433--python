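import numpy as np
import pytest

from thermolocus import (activation_shares, border_contributions,
                         derivative_profile, fragment_assay, perturb_trans,
                         predict, rate_derivative)
from thermolocus.io import ProfileTable
from thermolocus.params import GlobalParameters, ParameterSet, TFParameters
from thermolocus.synthetic import ProblemBundle


# --- numerical derivatives --------------------------------------------------

def test_inert_tf_has_negligible_derivative(bench):
    """A TF with all efficiencies zero and negligible binding (so no steric
    footprint either) cannot move the output."""
    _, bundle, params = bench
    inert = dict(params.tfs)
    inert["Rga"] = TFParameters("Rga", "repressor", A=1e-6, E_Q=0.0)
    p = ParameterSet(inert, params.globals_)
    d = derivative_profile(p, bundle, "Rga", h=1e-3)
    scale = np.abs(derivative_profile(p, bundle, "Rter", h=1e-3)).max()
    assert np.abs(d).max() < 1e-6 * scale


def test_derivative_estimates_converge_in_h(bench):
    _, bundle, params = bench
    d3 = derivative_profile(params, bundle, "Rter", h=1e-3)
    d6 = derivative_profile(params, bundle, "Rter", h=1e-6)
    scale = np.abs(d3).max()
    assert scale > 0
    assert np.max(np.abs(d3 - d6)) / scale < 1e-4


def test_convergence_sweep_estimates_agree(bench):
    from thermolocus import derivative_convergence
    _, bundle, params = bench
    sweep = derivative_convergence(params, bundle, "Rter",
                                   exponents=(-2, -4, -6))
    assert set(sweep) == {1e-2, 1e-4, 1e-6}
    ref = sweep[1e-6]
    scale = np.abs(ref).max()
    for est in sweep.values():
        assert np.max(np.abs(est - ref)) / scale < 1e-2


def test_rate_derivative_slices_the_profile(bench):
    _, bundle, params = bench
    d = derivative_profile(params, bundle, "Rter", h=1e-3)
    assert rate_derivative(params, bundle, "Rter", 30, h=1e-3) == d[30]


def test_forward_quotient_at_zero_concentration(bench):
    """Where [A] = 0 the derivative falls back to Newton's forward
    quotient (f(h) - f(0)) / h; verified against a manual recomputation."""
    _, bundle, params = bench
    zeroed = perturb_trans(bundle.profiles, [("Rga", "zero")])
    b0 = ProblemBundle(bundle.seq, bundle.pwms, zeroed, mode=bundle.mode,
                       threshold=bundle.threshold)
    h = 1e-3
    d = derivative_profile(params, b0, "Rga", h=h)
    at0 = predict(bundle.seq, bundle.pwms, params, zeroed).mRNA_pred
    up = perturb_trans(zeroed, [("Rga", "set_uniform", h)])
    ath = predict(bundle.seq, bundle.pwms, params, up).mRNA_pred
    assert np.all(np.isfinite(d))
    assert np.allclose(d, (ath - at0) / h, rtol=1e-9, atol=1e-12)


def test_symmetric_quotient_exact_on_linearised_response(bench):
    """Central differences are exact for responses linear in [A]; near-zero
    perturbations of an unbound TF's concentration behave linearly, so two
    very different h give matching slopes."""
    _, bundle, params = bench
    d_small = derivative_profile(params, bundle, "Uni", h=1e-5)
    d_large = derivative_profile(params, bundle, "Uni", h=1e-2)
    scale = np.abs(d_small).max()
    assert np.max(np.abs(d_small - d_large)) / scale < 5e-3


# --- border contributions ---------------------------------------------------

def test_uniform_tf_contributes_nothing_to_borders(bench):
    _, bundle, params = bench
    bc = border_contributions(params, bundle)
    inner = bc.contributions["Uni"][1:-1]       # Uni is spatially flat
    assert np.allclose(inner, 0.0, atol=1e-12)


def test_rising_repressor_contributes_negatively_on_flank(bench):
    _, bundle, params = bench
    bc = border_contributions(params, bundle)
    x = bundle.profiles.positions
    # Rter rises toward the posterior; on stripeB's posterior flank (~80-88%)
    # its contribution must be negative
    flank = (x >= 80) & (x <= 88)
    assert bc.contributions["Rter"][flank].max() < 0.0


def test_border_sum_matches_first_order_output_change(bench, bench_output):
    _, bundle, params = bench
    bc = border_contributions(params, bundle)
    total = sum(bc.contributions[tf] for tf in bc.tf_names)
    dR = np.gradient(bench_output.mRNA_pred)
    # compare where the output is actually changing
    moving = np.abs(dR) > 0.02 * np.abs(dR).max()
    rel = np.abs(total[moving] - dR[moving]) / np.abs(dR[moving])
    assert np.median(rel) < 0.10


def test_literal_average_reading_is_available(bench):
    _, bundle, params = bench
    bc = border_contributions(params, bundle, delta_mode="literal_average")
    a = bundle.profiles["Rter"]
    assert bc.delta["Rter"][5] == pytest.approx((a[4] + a[6]) / 2)
    with pytest.raises(ValueError):
        border_contributions(params, bundle, delta_mode="bogus")


# --- activation shares ------------------------------------------------------

def test_share_decomposition_is_exact(bench, bench_output):
    _, bundle, params = bench
    shares = activation_shares(params, bundle)
    total = sum(shares.N_a[tf] for tf in shares.tf_names)
    direct = (bench_output.N * bench_output.T).sum(axis=0)
    assert np.allclose(total, direct, rtol=1e-10, atol=1e-12)


def test_max_share_is_100_percent(bench):
    _, bundle, params = bench
    shares = activation_shares(params, bundle)
    peak = np.max(np.vstack([shares.percent[tf] for tf in shares.tf_names]),
                  axis=0)
    active = sum(shares.N_a[tf] for tf in shares.tf_names) > 0
    assert np.allclose(peak[active], 100.0)


def test_single_activator_gets_full_share():
    from thermolocus.synthetic import (SyntheticSpec, TFRoster, EnhancerPlan,
                                       make_problem, make_parameter_set)
    spec = SyntheticSpec(
        seed=4, locus_length=1500,
        tf_roster=(TFRoster("Solo", "activator", ("uniform", 1.0), level=0.5),),
        enhancers=(EnhancerPlan("e", 600, (("Solo", 0), ("Solo", 30))),),
        n_positions=10)
    bundle = make_problem(spec)
    params = make_parameter_set(spec, {"Solo": {"A": 0.02, "E_A": 8.0}})
    shares = activation_shares(params, bundle)
    assert np.allclose(shares.percent["Solo"], 100.0)


def test_dominant_activator_leads_where_its_sites_cluster(bench):
    _, bundle, params = bench
    shares = activation_shares(params, bundle)
    x = bundle.profiles.positions
    anterior = x <= 42  # stripeA is driven by the cooperative gradient TF
    assert np.all(shares.percent["Bia"][anterior] >
                  shares.percent["Hbl"][anterior])


# --- fragment assays --------------------------------------------------------

def test_fragment_equal_to_whole_locus_is_standardised_prediction(bench, bench_output):
    _, bundle, params = bench
    assay = fragment_assay(params, bundle.seq, bundle.pwms, bundle.profiles)
    assert assay.standardized.max() == pytest.approx(1.0)
    assert np.allclose(assay.standardized,
                       bench_output.mRNA_pred / bench_output.mRNA_pred.max())
    assert np.allclose(assay.output.mRNA_pred, bench_output.mRNA_pred)


def test_siteless_fragment_is_flat(bench):
    _, bundle, params = bench
    frag = bundle.seq.subsequence(2500, 2560)
    assay = fragment_assay(params, frag, bundle.pwms, bundle.profiles,
                           threshold=1e9)  # no sites callable
    assert np.allclose(assay.output.mRNA_pred, assay.output.mRNA_pred[0])


def test_planted_enhancer_fragment_reproduces_its_stripe(bench, bench_output):
    _, bundle, params = bench
    assay = fragment_assay(params, bundle.seq.subsequence(800, 1400),
                           bundle.pwms, bundle.profiles)
    x = bundle.profiles.positions
    assert assay.standardized.max() == pytest.approx(1.0)
    peak_at = x[np.argmax(assay.standardized)]
    locus_peakA = x[np.argmax(bench_output.mRNA_pred)]
    assert abs(peak_at - locus_peakA) <= 5.0
    assert assay.standardized[x >= 55].max() < 0.2   # silent elsewhere


def test_disjoint_fragments_subadditive_under_competition(bench, bench_output):
    _, bundle, params = bench
    a = fragment_assay(params, bundle.seq.subsequence(800, 1400),
                       bundle.pwms, bundle.profiles)
    b = fragment_assay(params, bundle.seq.subsequence(3800, 4400),
                       bundle.pwms, bundle.profiles)
    assert np.all(bench_output.mRNA_pred <
                  a.output.mRNA_pred + b.output.mRNA_pred)


# --- trans perturbations ----------------------------------------------------

def test_perturb_operations(bench):
    _, bundle, _ = bench
    table = bundle.profiles
    scaled = perturb_trans(table, [("Rter", "scale", 0.6)])
    assert np.allclose(scaled["Rter"], 0.6 * table["Rter"])
    uniform = perturb_trans(table, [("Hbl", "set_uniform", 120.0)])
    assert np.all(uniform["Hbl"] == 120.0)
    zeroed = perturb_trans(table, [("Bia", "zero")])
    assert np.all(zeroed["Bia"] == 0.0)
    ident = perturb_trans(table, [("Bia", "scale", 1.0)])
    assert np.array_equal(ident["Bia"], table["Bia"])
    # original untouched
    assert table["Rter"].max() > scaled["Rter"].max()
    with pytest.raises(KeyError):
        perturb_trans(table, [("NoSuch", "zero")])
    with pytest.raises(ValueError):
        perturb_trans(table, [("Bia", "frobnicate")])
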