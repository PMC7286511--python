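"""Maximum-likelihood fits, Fisher errors, model selection and diagnostics.

Published reference values are asserted at the resolution they were printed
(two decimals) with a +/-0.02 optimizer-determinism margin.
"""
import numpy as np
import pytest

from denshare.data import ExperimentSetup, ReplicateSeries, pool_replicates
from denshare.ensemble import ModelParams, multiplicity, partition
from denshare.inference import (
    fit,
    fit_mixed,
    fit_single_sex,
    joint_fit,
    kl_profile,
    log_likelihood,
    model_selection,
    observable_uncertainty,
    param_contrast,
)

TOL = 0.02


def test_female_interaction_estimate(ff_fit):
    u, se = ff_fit.estimate("u_ff")
    assert abs(u - 0.82) < TOL
    assert abs(se - 0.36) < 0.01
    assert ff_fit.active == ("u_ff",)  # mu traced out: no outsiders ever seen
    assert np.max(np.abs(ff_fit.moment_residuals)) < 1e-8


def test_male_interaction_combines_unequal_designs(mm_fit):
    """The all-male estimate weights the 5-pot and 6-pot replicates through
    the day-weighted free energy."""
    u, se = mm_fit.estimate("u_mm")
    assert abs(u - 3.45) < TOL
    assert abs(se - 0.66) < 0.01
    assert len(mm_fit.setups) == 2


@pytest.mark.parametrize(
    "key, name, est, se",
    [
        ("3a", "u_ff", 0.70, 0.49),
        ("3b", "u_ff", 0.96, 0.54),
        ("4a", "u_mm", 2.83, 0.85),
        ("4b", "u_mm", 4.15, 1.09),
    ],
)
def test_per_replicate_estimates(tables, key, name, est, se):
    r = fit_single_sex([tables[key]])
    e, s = r.estimate(name)
    assert abs(e - est) < TOL
    assert abs(s - se) < TOL


def test_single_replicate_equals_degenerate_combination(tables):
    """Combining with an absent second replicate changes nothing."""
    alone = fit_single_sex([tables["3a"]])
    # same replicate twice doubles M: same estimate, se shrinks by sqrt(2)
    doubled = fit_single_sex([tables["3a"], tables["3a"]])
    assert np.isclose(alone.params.u_ff, doubled.params.u_ff, atol=1e-9)
    assert np.isclose(alone.estimate("u_ff")[1], doubled.estimate("u_ff")[1] * np.sqrt(2), rtol=1e-6)


def test_loglik_at_neutral_params_matches_direct_multinomial(ff):
    """Independent oracle: at U = 0 with no outsiders the likelihood is the
    plain multinomial, W = sum log(g / N^K)."""
    reps = pool_replicates(ff)
    w = log_likelihood(reps, ModelParams())
    direct = sum(
        np.log(multiplicity(c) / 6.0**6) for r in reps for c in r.configs
    )
    assert np.isclose(w, direct, atol=1e-9)


def test_loglik_maximized_at_moment_matching_point(ff, ff_fit):
    reps = pool_replicates(ff)
    w0 = ff_fit.loglik
    for du in (-0.3, -0.05, 0.05, 0.3):
        p = ModelParams(u_ff=ff_fit.params.u_ff + du, traced=ff_fit.params.traced)
        assert log_likelihood(reps, p) < w0


def test_loglik_rejects_excluded_day(ff):
    reps = pool_replicates(ff)
    with pytest.raises(ValueError, match="day"):
        log_likelihood(reps, ModelParams(traced=frozenset({"u_ff"})))


def test_unattainable_moment_is_an_error():
    """A mean pair count above the U -> -inf supremum cannot be matched."""
    setup = ExperimentSetup(2, 0, 2, 1, 1)
    from denshare.data import OccupancyConfig

    # fake series whose empirical sigma exceeds the space maximum is
    # impossible to build (counts are consistent), so drive the error with
    # the attainability check directly: a single-config space has zero range
    cfg = OccupancyConfig((0, 2, 0), (0, 0, 0), experiment="x")
    series = ReplicateSeries(ExperimentSetup(2, 2, 0, 1, 1), (cfg,), "FF")
    # sigma_ff is always 1 here? no: space has configs with 0..1 pairs; a
    # series at the maximum (every day the double pot) hits the boundary
    with pytest.raises(ValueError, match="attainable"):
        fit([series])


def test_sex_contrast():
    t, p = param_contrast((0.82, 0.36), (3.45, 0.66))
    assert abs(t - 3.50) < 0.01
    assert p < 0.002  # at least as significant as published
    t0, p0 = param_contrast((1.0, 0.2), (1.0, 0.3))
    assert t0 == 0.0 and np.isclose(p0, 0.5)
    with pytest.raises(ValueError):
        param_contrast((1.0, 0.0), (2.0, 0.1))


def test_mixed_fit_pots_equal(fm_fit):
    """Combined mixed-sex fit: male-male interaction traced out (no male
    pair in 11 days), female outsiders allowed."""
    assert fm_fit.active == ("mu", "u_ff", "u_fm")
    assert "u_mm" in fm_fit.params.traced
    for name, est, se in [("mu", 2.59, 1.04), ("u_ff", 1.64, 0.81), ("u_fm", 1.49, 0.48)]:
        e, s = fm_fit.estimate(name)
        assert abs(e - est) < TOL
        assert abs(s - se) < TOL
    assert np.max(np.abs(fm_fit.moment_residuals)) < 1e-8


@pytest.mark.parametrize(
    "key, expected",
    [
        ("2a", {"mu": (2.87, 1.55), "u_ff": (3.15, 1.25), "u_mm": (1.35, 1.05), "u_fm": (-0.01, 0.94)}),
        ("2b", {"mu": (2.55, 1.42), "u_ff": (1.61, 0.85), "u_mm": (1.61, 1.10), "u_fm": (0.24, 0.83)}),
    ],
)
def test_mixed_fit_pots_limited(tables, key, expected):
    r = fit_mixed([tables[key]])
    assert set(r.active) == {"mu", "u_ff", "u_mm", "u_fm"}
    for name, (est, se) in expected.items():
        e, s = r.estimate(name)
        assert abs(e - est) < TOL
        assert abs(s - se) < TOL


def test_pooled_pots_limited_fit(tables):
    r = fit_mixed([tables["2a"], tables["2b"]])
    for name, est in [("mu", 2.90), ("u_ff", 2.16), ("u_mm", 1.33), ("u_fm", 0.28)]:
        assert abs(r.estimate(name)[0] - est) < TOL


def test_joint_fit_over_all_conditions(tables, ff, mm, fm):
    """All 45 days with shared parameters: both the joint likelihood and the
    inverse-variance average agree with the published combined set
    (3.83, 1.56, 2.61, 1.05) within its quoted errors, and with each other
    within one combined standard error."""
    jf = joint_fit({"FF": ff, "MM": mm, "FM": fm, "PL7": [tables["2a"]], "PL8": [tables["2b"]]})
    published = {"mu": (3.83, 0.52), "u_ff": (1.56, 0.31), "u_mm": (2.61, 0.42), "u_fm": (1.05, 0.31)}
    assert jf.joint.m_days == 45
    for name, (est, se) in published.items():
        e_joint, s_joint = jf.joint.estimate(name)
        e_wt, s_wt = jf.weighted_mean[name]
        assert abs(e_joint - est) <= se
        assert abs(e_joint - e_wt) <= np.hypot(s_joint, s_wt)
    # sexes contrast on the published combined values
    t, p = param_contrast((1.56, 0.31), (2.61, 0.42))
    assert abs(t - 2.01) < 0.01
    assert p < 0.025


def test_joint_fit_identical_replicates_equals_pooled(tables):
    a = tables["3a"]
    jf = joint_fit({"A": [a], "B": [a]})
    pooled = fit_single_sex([a, a])
    assert np.isclose(jf.joint.params.u_ff, pooled.params.u_ff, atol=1e-9)


def test_kl_argmin_matches_mle(ff, mm, ff_fit, mm_fit):
    """The KL divergence between the empirical and model sharing
    distributions is minimal at the moment-matching MLE (to within the grid
    step), and non-negative everywhere."""
    grid = np.round(np.arange(0.0, 6.0001, 0.05), 10)
    prof_f, argmin_f = kl_profile(ff, grid)
    prof_m, argmin_m = kl_profile(mm, grid)
    assert abs(argmin_f - ff_fit.params.u_ff) <= 0.05
    assert abs(argmin_m - mm_fit.params.u_mm) <= 0.05
    assert (prof_f["kl"] >= -1e-12).all()
    assert (prof_m["kl"] >= -1e-12).all()


def test_model_selection_table(ff):
    """The one-parameter on-site (Hubbard-type) Hamiltonian beats the
    sharing-linear and three-level families on small-sample AIC; the
    three-level family's likelihood is nearly degenerate with it."""
    ms = model_selection(ff).set_index("model")
    h1, h2, h3 = ms.loc["hubbard"], ms.loc["linear"], ms.loc["third"]
    assert abs(h1["params"]["u"] - 0.82) < TOL
    # AIC = -2 logL + 2p + 2p(p+1)/(M-p-1) holds exactly given the loglik
    assert np.isclose(h1["aic"], -2 * h1["loglik"] + 2 + 0.5, atol=1e-9)
    assert np.isclose(h1["bic"], -2 * h1["loglik"] + 2 * np.log(10), atol=1e-9)
    assert abs(h1["aic"] - 99.2512) < 0.05
    assert abs(h1["loglik"] - (-48.3756)) < 0.05
    # published comparison: the ordering is the substantive claim
    assert h1["aic"] < h2["aic"] < h3["aic"]
    assert h2["params"]["nu"] == 2
    # nesting: the three-level family contains the Hubbard energies up to a
    # gauge direction, so its maximized likelihood is at least as high
    assert h3["loglik"] >= h2["loglik"]
    assert abs(h3["loglik"] - (-48.3707)) < 0.01
    assert not h3["converged"]  # near-flat valley: flagged, as expected


def test_model_selection_requires_single_design(ff, mm):
    with pytest.raises(ValueError, match="single design"):
        model_selection(mm)  # mixes 5- and 6-pot replicates


def test_observable_uncertainty_structure(fm_fit):
    setup = fm_fit.setups[0]
    em_small = observable_uncertainty(setup, fm_fit.params, fm_fit.cov, fm_fit.active, 11)
    em_large = observable_uncertainty(setup, fm_fit.params, fm_fit.cov, fm_fit.active, 10**9)
    intrinsic = partition(setup, fm_fit.params).cov
    # the parameter-uncertainty inflation vanishes as M -> infinity
    assert np.allclose(em_large, intrinsic, atol=1e-6)
    # the correction is built from connected 4-point cumulants, which may be
    # slightly negative (sub-Gaussian observables): it inflates the leading
    # diagonals and never deflates any by more than a percent
    diag_s, diag_i = np.diag(em_small), np.diag(intrinsic)
    assert np.all(diag_s >= 0.99 * diag_i)
    assert diag_s[0] > diag_i[0] and diag_s[1] > diag_i[1]
    with pytest.raises(ValueError, match="active"):
        observable_uncertainty(setup, fm_fit.params, fm_fit.cov[:2, :2], fm_fit.active, 11)
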