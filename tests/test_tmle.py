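"""Targeting machinery: bounding, clever covariates, fluctuation, inference."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from targetmle import (
    LearnerSpec,
    OutcomeBounds,
    SimulationConfig,
    SingleLearner,
    TMLEError,
    bound_outcome,
    compute_clever_covariates,
    estimate_ate,
    fit_fluctuation,
    fit_initial_outcome,
    fit_propensity,
    generate_cohort,
    influence_curve,
    influence_curve_ci,
    tmle_ate,
    unbound_outcome,
    update_counterfactual_predictions,
)
from targetmle.cohort import design_matrix
from targetmle.tmle import Z975, g_computation


GLM_B = SingleLearner(LearnerSpec("glm", "binomial"))
GLM_G = SingleLearner(LearnerSpec("glm", "gaussian"))
MEAN_B = SingleLearner(LearnerSpec("mean_only", "binomial"))


# ---------------------------------------------------------------------------
# bounding

def test_bound_outcome_affine_map_and_median_magnitude():
    y_star, b = bound_outcome(np.array([0.0, 5.0, 10.0]))
    np.testing.assert_allclose(y_star, [0.0, 0.5, 1.0])
    assert (b.a, b.b) == (0.0, 10.0)
    # a cohort-scale value: day-5 median 15.9 against fixed bounds (0, 50)
    y_star, _ = bound_outcome(np.array([15.9]), OutcomeBounds(0.0, 50.0))
    assert y_star[0] == pytest.approx(0.318)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40, unique=True))
def test_bound_unbound_round_trip(vals):
    y = np.asarray(vals)
    y_star, b = bound_outcome(y)
    np.testing.assert_allclose(unbound_outcome(y_star, b), y,
                               rtol=1e-12, atol=1e-9)


def test_constant_outcome_is_an_error():
    with pytest.raises(TMLEError, match="constant"):
        bound_outcome(np.full(5, 3.3))


# ---------------------------------------------------------------------------
# nuisance fits

def test_mean_only_outcome_predictions_are_the_mean():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(40, 2))
    A = rng.binomial(1, 0.5, 40).astype(float)
    y_star = np.full(40, 0.5)
    Q_AW, Q_1W, Q_0W, _ = fit_initial_outcome(MEAN_B, W, A, y_star)
    for q in (Q_AW, Q_1W, Q_0W):
        np.testing.assert_allclose(q, 0.5)


def test_saturated_fit_recovers_cell_means():
    """One binary covariate, saturated interaction learner: the predictions
    equal the four observed cell means."""
    W = np.array([[0.0], [0.0], [1.0], [1.0]] * 6)
    A = np.array([0.0, 1.0, 0.0, 1.0] * 6)
    rng = np.random.default_rng(1)
    y_star = np.clip(0.3 + 0.2 * W[:, 0] + 0.25 * A + rng.normal(0, 0.02, 24),
                     0.01, 0.99)
    learner = SingleLearner(LearnerSpec("glm_interactions", "binomial"))
    Q_AW, Q_1W, Q_0W, _ = fit_initial_outcome(learner, W, A, y_star)
    for w in (0.0, 1.0):
        for a, Q in ((1.0, Q_1W), (0.0, Q_0W)):
            cell = (W[:, 0] == w) & (A == a)
            np.testing.assert_allclose(Q[(W[:, 0] == w)].mean(),
                                       y_star[cell].mean(), atol=1e-6)
    match = np.where(A == 1, Q_1W, Q_0W)
    np.testing.assert_allclose(Q_AW, match, rtol=1e-12)


def test_intercept_only_propensity_is_the_arm_fraction():
    A = np.array([1.0] * 128 + [0.0] * 40)
    W = np.zeros((168, 1))
    g, _ = fit_propensity(MEAN_B, W, A)
    np.testing.assert_allclose(g, 128 / 168)


def test_one_arm_only_raises_positivity_error():
    with pytest.raises(TMLEError, match="one treatment arm"):
        fit_propensity(GLM_B, np.zeros((10, 1)), np.ones(10))


def test_separable_propensity_is_clipped_at_g_bounds():
    rng = np.random.default_rng(2)
    W = np.linspace(-3, 3, 60)[:, None]
    A = (W[:, 0] > 0).astype(float)
    g, n_trunc = fit_propensity(GLM_B, W, A, g_bounds=(0.025, 0.975))
    assert g.min() >= 0.025 and g.max() <= 0.975
    assert n_trunc > 0


# ---------------------------------------------------------------------------
# clever covariates and fluctuation

def test_clever_covariate_arithmetic():
    H1, H0 = compute_clever_covariates(np.array([1.0, 0.0]),
                                       np.array([0.5, 0.8]))
    np.testing.assert_allclose(H1, [2.0, 0.0])
    np.testing.assert_allclose(H0, [0.0, 5.0])


def test_clever_covariates_average_to_one_under_randomisation():
    rng = np.random.default_rng(3)
    n = 100_000
    p = 0.3
    A = rng.binomial(1, p, n).astype(float)
    H1, H0 = compute_clever_covariates(A, np.full(n, p))
    assert abs(H1.mean() - 1) < 3 / np.sqrt(n * p / (1 - p))
    assert abs(H0.mean() - 1) < 3 / np.sqrt(n * (1 - p) / p)


def _hand_fixture():
    """Six frozen rows for oracle comparison."""
    y_star = np.array([0.62, 0.15, 0.88, 0.40, 0.55, 0.71])
    Q_AW = np.array([0.50, 0.22, 0.80, 0.47, 0.60, 0.66])
    A = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
    g = np.array([0.70, 0.35, 0.80, 0.25, 0.55, 0.62])
    return y_star, Q_AW, A, g


def test_fluctuation_matches_independent_offset_logistic_fit():
    """Oracle: statsmodels GLM with offset, scripted independently."""
    y_star, Q_AW, A, g = _hand_fixture()
    H1, H0 = compute_clever_covariates(A, g)
    fit = fit_fluctuation(y_star, Q_AW, H1, H0, mode="two_eps")
    oracle = sm.GLM(y_star, np.column_stack([H1, H0]),
                    family=sm.families.Binomial(),
                    offset=logit(Q_AW)).fit(maxiter=200, tol=1e-12)
    np.testing.assert_allclose(fit.eps, oracle.params, atol=1e-8)
    Q1 = np.clip(Q_AW + 0.02, 0.05, 0.95)
    Q0 = np.clip(Q_AW - 0.03, 0.05, 0.95)
    Qs1, Qs0 = update_counterfactual_predictions(Q1, Q0, g, fit)
    e1, e0 = oracle.params
    np.testing.assert_allclose(Qs1, expit(logit(Q1) + e1 / g), atol=1e-8)
    np.testing.assert_allclose(Qs0, expit(logit(Q0) + e0 / (1 - g)), atol=1e-8)


def test_one_eps_mode_matches_single_covariate_oracle():
    y_star, Q_AW, A, g = _hand_fixture()
    H1, H0 = compute_clever_covariates(A, g)
    fit = fit_fluctuation(y_star, Q_AW, H1, H0, mode="one_eps")
    oracle = sm.GLM(y_star, (H1 - H0)[:, None], family=sm.families.Binomial(),
                    offset=logit(Q_AW)).fit(maxiter=200, tol=1e-12)
    np.testing.assert_allclose(fit.eps, oracle.params, atol=1e-8)


def test_epsilon_vanishes_when_initial_fit_is_already_targeted():
    """If Q already solves the score equations, the fluctuation is null."""
    rng = np.random.default_rng(4)
    n = 500
    A = rng.binomial(1, 0.5, n).astype(float)
    g = np.full(n, 0.5)
    Q_AW = np.clip(rng.uniform(0.2, 0.8, n), 0.01, 0.99)
    y_star = Q_AW.copy()  # residuals identically zero
    H1, H0 = compute_clever_covariates(A, g)
    fit = fit_fluctuation(y_star, Q_AW, H1, H0)
    assert max(abs(e) for e in fit.eps) < 1e-6


def test_score_identity_after_fluctuation():
    y_star, Q_AW, A, g = _hand_fixture()
    H1, H0 = compute_clever_covariates(A, g)
    fit = fit_fluctuation(y_star, Q_AW, H1, H0)
    e1, e0 = fit.eps
    Q_star = expit(logit(Q_AW) + e1 * H1 + e0 * H0)
    assert abs(np.mean(H1 * (y_star - Q_star))) < 1e-8
    assert abs(np.mean(H0 * (y_star - Q_star))) < 1e-8


def test_zero_epsilon_update_is_the_identity_and_stays_in_unit_interval():
    y_star, Q_AW, A, g = _hand_fixture()
    from targetmle.tmle import FluctuationFit
    H1, H0 = compute_clever_covariates(A, g)
    null_fit = FluctuationFit(H1=H1, H0=H0, eps=(0.0, 0.0), mode="two_eps",
                              trace=[])
    Qs1, Qs0 = update_counterfactual_predictions(Q_AW, Q_AW, g, null_fit)
    np.testing.assert_array_equal(Qs1, Q_AW)
    np.testing.assert_array_equal(Qs0, Q_AW)
    big_fit = FluctuationFit(H1=H1, H0=H0, eps=(25.0, -25.0), mode="two_eps",
                             trace=[])
    Qs1, Qs0 = update_counterfactual_predictions(Q_AW, Q_AW, g, big_fit)
    assert (Qs1 > 0).all() and (Qs1 < 1).all()
    assert (Qs0 > 0).all() and (Qs0 < 1).all()


# ---------------------------------------------------------------------------
# estimate and inference

def test_ate_rescaling_arithmetic():
    b = OutcomeBounds(0.0, 50.0)
    assert estimate_ate(np.full(10, 0.6), np.full(10, 0.4), b) == \
        pytest.approx(10.0)
    assert estimate_ate(np.full(10, 0.5), np.full(10, 0.5), b) == 0.0


def test_influence_curve_is_centred():
    y_star, Q_AW, A, g = _hand_fixture()
    H1, H0 = compute_clever_covariates(A, g)
    fit = fit_fluctuation(y_star, Q_AW, H1, H0)
    Qs1, Qs0 = update_counterfactual_predictions(Q_AW, Q_AW, g, fit)
    Q_star = np.where(A == 1, Qs1, Qs0)
    psi_star = np.mean(Qs1 - Qs0)
    D = influence_curve(y_star, A, Q_star, Qs1, Qs0, g, psi_star)
    assert abs(D.mean()) < 1e-10


def test_estimate_renders_like_a_published_row():
    from targetmle import ATEEstimate
    est = ATEEstimate.from_psi_se(1.2454, 1.5953, n=168)
    text = est.format()
    assert text == (f"{est.psi:.3f} {est.se:.3f} s.e "
                    f"[{est.ci_low:.3f},{est.ci_high:.3f}]")
    import re
    assert re.fullmatch(r"-?\d+\.\d{3} \d+\.\d{3} s\.e "
                        r"\[-?\d+\.\d{3},-?\d+\.\d{3}\]", text)


def test_ci_uses_fixed_normal_quantile():
    from targetmle import ATEEstimate
    est = ATEEstimate.from_psi_se(2.0, 0.5, n=100)
    assert est.ci_low == pytest.approx(2.0 - 1.959964 * 0.5)
    assert est.ci_high == pytest.approx(2.0 + 1.959964 * 0.5)


# ---------------------------------------------------------------------------
# end-to-end estimator

def test_missing_values_direct_user_to_imputation(small_cohort):
    cohort, _ = small_cohort
    broken = cohort.copy()
    broken.loc[3, "nlr_d5"] = np.nan
    with pytest.raises(Exception, match="imputation|complete_case"):
        tmle_ate(broken, GLM_B, GLM_B)


def test_affine_equivariance_of_psi_and_z(small_cohort):
    """Rescaling the outcome by y -> c*y + d multiplies psi by c exactly
    and leaves the z-statistic untouched."""
    cohort, _ = small_cohort
    est = tmle_ate(cohort, GLM_B, GLM_B, seed=1)
    scaled = cohort.copy()
    c, d = 3.5, 12.0
    scaled["nlr_d5"] = c * scaled["nlr_d5"] + d
    scaled["neut_d5"] = scaled["nlr_d5"] * scaled["lymph_d5"]
    est2 = tmle_ate(scaled, GLM_B, GLM_B, seed=1)
    assert est2.psi == pytest.approx(c * est.psi, abs=1e-10 * max(1, abs(est.psi)))
    assert est2.z == pytest.approx(est.z, abs=1e-10)


def test_zero_fluctuation_reduces_to_g_computation(small_cohort):
    """Forcing eps = 0 must reproduce the plug-in G-computation estimate."""
    cohort, _ = small_cohort
    W, _ = design_matrix(cohort)
    A = cohort["treatment"].to_numpy(float)
    y = cohort["nlr_d5"].to_numpy(float)
    y_star, bounds = bound_outcome(y)
    Q_AW, Q_1W, Q_0W, _ = fit_initial_outcome(GLM_B, W, A, y_star, seed=0)
    from targetmle.tmle import FluctuationFit
    g, _ = fit_propensity(GLM_B, W, A, seed=1)
    H1, H0 = compute_clever_covariates(A, g)
    null_fit = FluctuationFit(H1=H1, H0=H0, eps=(0.0, 0.0), mode="two_eps",
                              trace=[])
    Qs1, Qs0 = update_counterfactual_predictions(Q_1W, Q_0W, g, null_fit)
    assert estimate_ate(Qs1, Qs0, bounds) == g_computation(Q_1W, Q_0W, bounds)


def test_null_effect_yields_insignificant_estimate():
    df, _ = generate_cohort(SimulationConfig(n=5000, tau=0.0, seed=77))
    est = tmle_ate(df, GLM_G, GLM_B, seed=2)
    assert abs(est.psi) < 3 * est.se


def test_diagnostics_report_positivity_and_scores(small_cohort):
    cohort, _ = small_cohort
    est, diag = tmle_ate(cohort, GLM_B, GLM_B, seed=3, return_diagnostics=True)
    assert sum(diag.g_histogram[0]) == len(cohort)
    assert abs(diag.score_h1) < 1e-8 and abs(diag.score_h0) < 1e-8
    assert abs(diag.mean_eic) < 1e-10
    assert est.ci_low < est.psi < est.ci_high


def test_one_eps_mode_runs_end_to_end(small_cohort):
    cohort, truth = small_cohort
    est = tmle_ate(cohort, GLM_G, GLM_B, mode="one_eps", seed=4)
    assert abs(est.psi - truth.true_ate) < 4 * est.se
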