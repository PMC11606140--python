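"""Fold construction, CV stacking, meta-learner optimality and ordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetmle import (
    LearnerError,
    LearnerSpec,
    cross_validated_predictions,
    default_library,
    fit_learner,
    fit_meta_discrete,
    fit_meta_nnls,
    fit_super_learner,
    make_folds,
)
from targetmle.learners import _risk


# ---------------------------------------------------------------------------
# folds

def test_exact_division_gives_equal_folds():
    folds = make_folds(10, 5, seed=0)
    assert sorted(np.bincount(folds)) == [2] * 5


def test_pigeonhole_fold_sizes_for_168_rows_in_10_folds():
    sizes = sorted(np.bincount(make_folds(168, 10, seed=1)))
    assert sizes == [16, 16] + [17] * 8


def test_stratified_folds_balance_the_minority_class():
    strat = np.array([0] * 128 + [1] * 40)
    folds = make_folds(168, 10, stratify_on=strat, seed=2)
    for v in range(10):
        assert (strat[folds == v] == 1).sum() == 4
    assert sorted(np.bincount(folds)) == [16, 16] + [17] * 8


def test_folds_deterministic_and_v_bounds_enforced():
    assert (make_folds(50, 7, seed=3) == make_folds(50, 7, seed=3)).all()
    with pytest.raises(LearnerError):
        make_folds(5, 6)
    with pytest.raises(LearnerError):
        make_folds(5, 1)


# ---------------------------------------------------------------------------
# cross-validated predictions

def test_mean_only_cv_column_is_foldwise_training_means():
    rng = np.random.default_rng(0)
    y = rng.normal(size=30)
    X = rng.normal(size=(30, 2))
    folds = make_folds(30, 3, seed=0)
    Z, kept = cross_validated_predictions([LearnerSpec("mean_only", "gaussian")],
                                          X, y, folds)
    assert kept == [0]
    for v in range(3):
        np.testing.assert_allclose(Z[folds == v, 0], y[folds != v].mean())


def test_leave_one_out_interpolates_noiseless_linear_data():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 2))
    y = X @ [2.0, -1.0] + 0.5
    folds = make_folds(12, 12, seed=0)
    Z, _ = cross_validated_predictions([LearnerSpec("glm", "gaussian")],
                                       X, y, folds)
    np.testing.assert_allclose(Z[:, 0], y, atol=1e-8)


def test_cv_matrix_matches_scripted_fold_by_fold_refits():
    """Brute-force oracle: refit each learner per fold by hand."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(24, 3))
    y = X @ [1.0, 0.0, -2.0] + rng.normal(0, 0.3, 24)
    library = [LearnerSpec("mean_only", "gaussian"), LearnerSpec("glm", "gaussian")]
    folds = make_folds(24, 4, seed=5)
    Z, kept = cross_validated_predictions(library, X, y, folds, seed=7)
    oracle = np.empty_like(Z)
    for l, spec in enumerate(library):
        for v in range(4):
            tr = folds != v
            fit = fit_learner(spec, X[tr], y[tr], seed=7 + 31 * l)
            oracle[~tr, l] = fit.predict(X[~tr])
    np.testing.assert_allclose(Z, oracle, rtol=1e-12)


# ---------------------------------------------------------------------------
# meta-learners

def test_perfect_column_gets_full_weight():
    rng = np.random.default_rng(3)
    y = rng.normal(size=20)
    Z = np.column_stack([y, y + rng.normal(0, 1, 20)])
    w = fit_meta_nnls(Z, y)
    assert w[0] == pytest.approx(1.0, abs=1e-6)


def test_identical_columns_tie_at_the_single_column_risk():
    rng = np.random.default_rng(4)
    y = rng.normal(size=25)
    col = y + rng.normal(0, 0.5, 25)
    Z = np.column_stack([col, col, col])
    w = fit_meta_nnls(Z, y)
    risk = np.mean((y - Z @ w) ** 2)
    assert risk == pytest.approx(np.mean((y - col) ** 2), rel=1e-9)


def test_nnls_weights_match_simplex_grid_search_risk():
    """Grid-search oracle over the simplex at 1e-3 resolution."""
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, 6)
    Z = np.column_stack([y + rng.normal(0, 0.4, 6),
                         y + rng.normal(0, 0.6, 6),
                         rng.normal(0, 1, 6)])
    w = fit_meta_nnls(Z, y)
    risk = np.mean((y - Z @ w) ** 2)
    step = 1e-3
    grid = np.arange(0, 1 + step / 2, step)
    best = np.inf
    for w1 in grid:
        w2 = np.arange(0, 1 - w1 + step / 2, step)
        w3 = 1 - w1 - w2
        preds = np.outer(Z[:, 0], np.full_like(w2, w1)) + \
            np.outer(Z[:, 1], w2) + np.outer(Z[:, 2], w3)
        risks = np.mean((y[:, None] - preds) ** 2, axis=0)
        best = min(best, risks.min())
    assert risk <= best + 1e-9
    assert abs(risk - best) < 1e-6


def test_both_solvers_agree_in_achieved_risk():
    rng = np.random.default_rng(6)
    y = rng.normal(size=40)
    Z = np.column_stack([y + rng.normal(0, s, 40) for s in (0.3, 0.5, 1.0)])
    r1 = np.mean((y - Z @ fit_meta_nnls(Z, y, solver="nnls")) ** 2)
    r2 = np.mean((y - Z @ fit_meta_nnls(Z, y, solver="auglag")) ** 2)
    assert abs(r1 - r2) < 1e-6


def test_discrete_selector_and_tie_rule():
    np.testing.assert_array_equal(fit_meta_discrete([2.0, 1.0, 3.0]),
                                  [0.0, 1.0, 0.0])
    np.testing.assert_array_equal(fit_meta_discrete([1.0, 1.0]), [1.0, 0.0])
    with pytest.raises(LearnerError):
        fit_meta_discrete([np.nan, np.inf])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_simplex_and_risk_ordering_invariants(seed):
    """Weights live on the simplex; the convex ensemble's CV risk never
    exceeds the discrete winner's, which never exceeds any base risk."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=30)
    Z = rng.normal(size=(30, 4)) + y[:, None] * rng.uniform(0, 1, 4)
    w = fit_meta_nnls(Z, y)
    assert (w >= -1e-12).all()
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    col_risks = np.mean((y[:, None] - Z) ** 2, axis=0)
    ens = np.mean((y - Z @ w) ** 2)
    assert ens <= col_risks.min() + 1e-9


# ---------------------------------------------------------------------------
# full super learner

def _toy_regression(n=150, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = 0.5 + X @ [0.3, -0.2, 0.1] + rng.normal(0, 0.1, n)
    y = (y - y.min()) / (y.max() - y.min())
    return X, y


def test_singleton_library_reduces_to_the_single_learner():
    X, y = _toy_regression()
    spec = LearnerSpec("glm", "gaussian")
    for meta in ("nnls", "discrete"):
        sl = fit_super_learner([spec], X, y, V=5, meta=meta, seed=3)
        direct = fit_learner(spec, X, y, seed=3)
        np.testing.assert_allclose(sl.predict(X), direct.predict(X), rtol=1e-12)


def test_dominant_learner_selected_by_both_metas():
    """On linear data the main-terms GLM dominates; discrete and convex
    metas then produce (nearly) identical predictions."""
    X, y = _toy_regression(n=400, seed=1)
    lib = [LearnerSpec("mean_only", "gaussian"), LearnerSpec("glm", "gaussian")]
    dsl = fit_super_learner(lib, X, y, V=5, meta="discrete", seed=2)
    nnls = fit_super_learner(lib, X, y, V=5, meta="nnls", seed=2)
    assert dsl.weights[1] == 1.0
    assert nnls.weights[1] > 0.99
    np.testing.assert_allclose(dsl.predict(X), nnls.predict(X), atol=1e-3)


@pytest.mark.parametrize("family", ["gaussian", "binomial"])
def test_full_stack_risk_ordering(family):
    rng = np.random.default_rng(11)
    X = rng.normal(size=(200, 3))
    if family == "gaussian":
        y = X @ [0.4, 0.2, -0.1] + rng.normal(0, 0.3, 200)
        y = (y - y.min()) / (y.max() - y.min())
    else:
        from scipy.special import expit
        y = rng.binomial(1, expit(X @ [0.8, -0.5, 0.2])).astype(float)
    lib = default_library(family)
    nnls = fit_super_learner(lib, X, y, V=5, meta="nnls", seed=4)
    dsl = fit_super_learner(lib, X, y, V=5, meta="discrete", seed=4)
    assert nnls.cv_risk_ensemble <= dsl.cv_risk_ensemble + 1e-9
    assert (dsl.cv_risk_ensemble <= nnls.cv_risks + 1e-9).all()


def test_binomial_predictions_clipped_into_open_unit_interval():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(80, 2))
    y = (X[:, 0] > 0).astype(float)  # separable: raw GLM would saturate
    sl = fit_super_learner(default_library("binomial"), X, y, V=4, seed=5)
    p = sl.predict(X)
    assert (p > 0).all() and (p < 1).all()


def test_model_class_member_recovered_by_discrete_selector():
    """Data generated by one library member's model class: the discrete
    meta picks that member in nearly every realisation."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(600, 3))
        y = 0.3 + X @ [0.5, -0.4, 0.2] + rng.normal(0, 0.2, 600)
        y = (y - y.min()) / (y.max() - y.min())
        lib = [LearnerSpec("mean_only", "gaussian"),
               LearnerSpec("glm", "gaussian"),
               LearnerSpec("tree_ensemble", "gaussian")]
        dsl = fit_super_learner(lib, X, y, V=5, meta="discrete", seed=seed)
        hits += int(dsl.weights[1] == 1.0)
    assert hits >= 9
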