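"""Pluggable regression learners and a cross-validated super learner.

The super learner stacks a library of base learners by V-fold cross
validation.  Two meta-learners are provided: the convex (simplex-weighted)
combination minimising cross-validated risk, and the discrete winner-take-
all selector picking the single base learner with the lowest CV risk.  For
gaussian outcomes the CV risk is mean squared error and the convex meta
problem is simplex-constrained least squares; for binomial outcomes the
risk is the negative Bernoulli (quasi-)log-likelihood, minimised over the
simplex on the probability scale.  Both objectives are convex, so the
convex ensemble's CV risk can never exceed that of any single learner.

Two solvers are exposed for the convex meta problem: ``"nnls"`` (active-set
non-negative least squares, normalised, then polished on the simplex with
SLSQP) and ``"auglag"`` (constrained minimisation via trust-constr, an
augmented-Lagrangian-style method).  They agree in achieved risk to high
precision; the flag exists for cross-checking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize, nnls as _active_set_nnls
from scipy.special import expit
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.preprocessing import PolynomialFeatures

logger = logging.getLogger(__name__)

KINDS = ("mean_only", "glm", "glm_interactions", "tree_ensemble")
FAMILIES = ("gaussian", "binomial")

#: probability clipping for binomial-family predictions
PROB_CLIP = (1e-6, 1.0 - 1e-6)

_TREE_DEFAULTS = dict(n_estimators=100, max_depth=3, learning_rate=0.1, subsample=1.0)


class LearnerError(RuntimeError):
    """A learner (or every learner in a library) failed to fit."""


@dataclass(frozen=True)
class LearnerSpec:
    """Declaration of a base learner: model kind, outcome family, knobs."""

    kind: str
    family: str
    hyperparameters: tuple = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise LearnerError(f"unknown learner kind {self.kind!r}")
        if self.family not in FAMILIES:
            raise LearnerError(f"unknown family {self.family!r}")
        if isinstance(self.hyperparameters, Mapping):
            object.__setattr__(self, "hyperparameters",
                               tuple(sorted(self.hyperparameters.items())))

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


def default_library(family: str) -> list[LearnerSpec]:
    """Default base-learner stack: a constant, two GLMs, a tree ensemble."""
    return [
        LearnerSpec("mean_only", family),
        LearnerSpec("glm", family),
        LearnerSpec("glm_interactions", family),
        LearnerSpec("tree_ensemble", family),
    ]


class FittedLearner:
    """A fitted base learner; prediction is a pure function of covariates."""

    def __init__(self, spec: LearnerSpec, predict_fn, fingerprint: str):
        self.spec = spec
        self._predict_fn = predict_fn
        self.fingerprint = fingerprint

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        pred = np.asarray(self._predict_fn(X), float)
        if self.spec.family == "binomial":
            pred = np.clip(pred, *PROB_CLIP)
        return pred


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _fit_binomial_glm(X1: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Quasi-binomial GLM coefficients with a ridge fallback on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X1, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200, tol=1e-10)
            params = np.asarray(res.params, float)
            if not np.all(np.isfinite(params)):
                raise ValueError("non-finite GLM coefficients")
        except Exception:
            res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, maxiter=500)
            params = np.asarray(res.params, float)
            if not np.all(np.isfinite(params)):
                raise LearnerError("binomial GLM failed even with ridge fallback")
    return params


def fit_learner(spec: LearnerSpec, X, y, seed: int = 0) -> FittedLearner:
    """Fit a single base learner; deterministic given ``seed``."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if len(X) != len(y):
        raise LearnerError("X and y are not conformable")
    if spec.family == "binomial" and ((y < 0) | (y > 1)).any():
        raise LearnerError("binomial-family targets must lie in [0,1]")
    fingerprint = f"{spec.kind}/{spec.family}/n={len(y)}/seed={seed}"

    if spec.kind == "mean_only":
        m = float(y.mean())
        return FittedLearner(spec, lambda Z, m=m: np.full(len(Z), m), fingerprint)

    if spec.kind in ("glm", "glm_interactions"):
        if spec.kind == "glm_interactions":
            poly = PolynomialFeatures(degree=2, interaction_only=True,
                                      include_bias=False)
            Xd = poly.fit_transform(X)
            transform = poly.transform
        else:
            Xd = X
            transform = lambda Z: Z
        X1 = _add_intercept(Xd)
        if spec.family == "gaussian":
            beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
            return FittedLearner(
                spec,
                lambda Z, b=beta, t=transform: _add_intercept(t(Z)) @ b,
                fingerprint)
        beta = _fit_binomial_glm(X1, y)
        return FittedLearner(
            spec,
            lambda Z, b=beta, t=transform: expit(_add_intercept(t(Z)) @ b),
            fingerprint)

    if spec.kind == "tree_ensemble":
        hp = dict(_TREE_DEFAULTS)
        hp.update(spec.hp)
        model = GradientBoostingRegressor(random_state=seed, **hp)
        model.fit(X, y)
        return FittedLearner(spec, model.predict, fingerprint)

    raise LearnerError(f"unknown learner kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# cross validation

def make_folds(n: int, V: int, stratify_on: Optional[Sequence] = None,
               seed: int = 0) -> np.ndarray:
    """Partition ``{0..n-1}`` into V folds of sizes differing by at most 1.

    With ``stratify_on`` (a discrete vector), each level's per-fold counts
    also differ by at most 1.  Deterministic given ``seed``.
    """
    if V < 2 or V > n:
        raise LearnerError(f"need 2 <= V <= n, got V={V}, n={n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratify_on is None:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % V
        return folds
    s = np.asarray(stratify_on)
    if len(s) != n:
        raise LearnerError("stratify_on length mismatch")
    fold_order = rng.permutation(V)
    cursor = 0
    for level in np.unique(s):
        idx = rng.permutation(np.flatnonzero(s == level))
        for j, i in enumerate(idx):
            folds[i] = fold_order[(cursor + j) % V]
        cursor += len(idx)
    return folds


def _risk(pred: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.mean((y - pred) ** 2))
    p = np.clip(pred, *PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def cross_validated_predictions(library: Sequence[LearnerSpec], X, y,
                                folds: np.ndarray, seed: int = 0
                                ) -> tuple[np.ndarray, list[int]]:
    """Out-of-fold prediction matrix Z (n x L_kept).

    Entry (i, l) is learner l's prediction for row i from the fit that
    excluded row i's fold.  A learner failing on any fold is dropped with a
    logged warning; the second return value lists surviving library
    indices.  All learners failing is an error.
    """
    if len(library) == 0:
        raise LearnerError("empty learner library")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    cols, kept = [], []
    for l, spec in enumerate(library):
        col = np.empty(n)
        try:
            for v in np.unique(folds):
                train = folds != v
                fit = fit_learner(spec, X[train], y[train], seed=seed + 31 * l)
                col[~train] = fit.predict(X[~train])
        except Exception as exc:  # noqa: BLE001 - any failure drops the learner
            logger.warning("dropping learner %s: %s", spec.kind, exc)
            continue
        cols.append(col)
        kept.append(l)
    if not kept:
        raise LearnerError("every learner in the library failed")
    return np.column_stack(cols), kept


# ---------------------------------------------------------------------------
# meta learners

def _simplex_minimize(objective, jac, L: int, starts, solver: str) -> np.ndarray:
    cons_sum = {"type": "eq", "fun": lambda w: w.sum() - 1.0,
                "jac": lambda w: np.ones_like(w)}
    bounds = [(0.0, 1.0)] * L
    best_w, best_f = None, np.inf
    for w0 in starts:
        if solver == "auglag":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(objective, w0, jac=jac, method="trust-constr",
                               bounds=bounds,
                               constraints=[{"type": "eq",
                                             "fun": lambda w: w.sum() - 1.0}],
                               options={"gtol": 1e-12, "xtol": 1e-12,
                                        "maxiter": 500})
        else:
            res = minimize(objective, w0, jac=jac, method="SLSQP",
                           bounds=bounds, constraints=[cons_sum],
                           options={"ftol": 1e-14, "maxiter": 500})
        w = np.clip(np.asarray(res.x, float), 0.0, None)
        if w.sum() <= 0:
            continue
        w = w / w.sum()
        f = objective(w)
        if f < best_f:
            best_w, best_f = w, f
    return best_w


def fit_meta_nnls(Z, y, solver: str = "nnls") -> np.ndarray:
    """Simplex weights minimising ``||y - Z w||^2`` over ``w >= 0, sum w = 1``.

    Starts from the active-set NNLS solution (normalised); if that solution
    is identically zero, falls back to the one-hot selector at the
    best-risk column (logged).  The achieved risk never exceeds that of any
    single column.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    y = np.asarray(y, float)
    if not np.all(np.isfinite(Z)):
        raise LearnerError("non-finite entries in the prediction matrix")
    n, L = Z.shape
    col_risk = np.mean((y[:, None] - Z) ** 2, axis=0)
    one_hot = np.zeros(L)
    one_hot[int(np.argmin(col_risk))] = 1.0
    if L == 1:
        return np.ones(1)

    w_raw, _ = _active_set_nnls(Z, y)
    if w_raw.sum() <= 0:
        logger.warning("NNLS returned the zero vector; falling back to the "
                       "discrete selector")
        return one_hot
    starts = [w_raw / w_raw.sum(), np.full(L, 1.0 / L), one_hot.copy()]

    def objective(w):
        r = y - Z @ w
        return float(r @ r) / n

    def jac(w):
        return -2.0 * (Z.T @ (y - Z @ w)) / n

    w = _simplex_minimize(objective, jac, L, starts, solver)
    if w is None or objective(w) > col_risk.min():
        return one_hot
    return w


def _fit_meta_nll(Z, y, solver: str = "nnls") -> np.ndarray:
    """Simplex weights minimising the Bernoulli negative log-likelihood."""
    Z = np.clip(np.atleast_2d(np.asarray(Z, float)), *PROB_CLIP)
    y = np.asarray(y, float)
    n, L = Z.shape
    col_risk = np.array([_risk(Z[:, j], y, "binomial") for j in range(L)])
    one_hot = np.zeros(L)
    one_hot[int(np.argmin(col_risk))] = 1.0
    if L == 1:
        return np.ones(1)

    def objective(w):
        p = np.clip(Z @ w, *PROB_CLIP)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))

    def jac(w):
        p = np.clip(Z @ w, *PROB_CLIP)
        g = (p - y) / (p * (1 - p))
        return (Z.T @ g) / n

    starts = [np.full(L, 1.0 / L), one_hot.copy()]
    w = _simplex_minimize(objective, jac, L, starts, solver)
    if w is None or objective(w) > col_risk.min():
        return one_hot
    return w


def fit_meta_discrete(cv_risks) -> np.ndarray:
    """Winner-take-all selector: one-hot at the minimal CV risk.

    Ties break toward the lowest library index (logged).
    """
    risks = np.asarray(cv_risks, float)
    finite = np.isfinite(risks)
    if not finite.any():
        raise LearnerError("all CV risks are non-finite")
    masked = np.where(finite, risks, np.inf)
    winner = int(np.argmin(masked))
    if (masked == masked[winner]).sum() > 1:
        logger.warning("CV-risk tie; selecting lowest library index %d", winner)
    sel = np.zeros(len(risks))
    sel[winner] = 1.0
    return sel


@dataclass
class SuperLearnerFit:
    """A fitted super learner: CV diagnostics plus full-data base refits."""

    library: list[LearnerSpec]
    folds: np.ndarray
    cv_risks: np.ndarray
    meta: str
    weights: np.ndarray
    family: str
    fitted_learners: list[FittedLearner] = field(repr=False, default_factory=list)
    cv_risk_ensemble: float = np.nan

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack([f.predict(X) for f in self.fitted_learners])
        out = preds @ self.weights
        if self.family == "binomial":
            out = np.clip(out, *PROB_CLIP)
        return out

    def diagnostics_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "learner": [s.kind for s in self.library],
            "cv_risk": self.cv_risks,
            "weight": self.weights,
        })


def fit_super_learner(library: Sequence[LearnerSpec], X, y, V: int = 10,
                      meta: str = "nnls", seed: int = 0,
                      stratify: str = "auto",
                      solver: str = "nnls") -> SuperLearnerFit:
    """V-fold super learner: folds -> CV predictions -> meta fit -> refits."""
    if meta not in ("nnls", "discrete"):
        raise LearnerError(f"meta must be 'nnls' or 'discrete', got {meta!r}")
    library = list(library)
    families = {s.family for s in library}
    if len(families) != 1:
        raise LearnerError("library mixes outcome families")
    family = families.pop()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)

    stratify_on = None
    if stratify == "auto" and family == "binomial" and set(np.unique(y)) <= {0.0, 1.0}:
        stratify_on = y
    folds = make_folds(len(y), V, stratify_on=stratify_on, seed=seed)
    Z, kept = cross_validated_predictions(library, X, y, folds, seed=seed)
    kept_specs = [library[l] for l in kept]
    cv_risks = np.array([_risk(Z[:, j], y, family) for j in range(Z.shape[1])])

    if meta == "discrete":
        weights = fit_meta_discrete(cv_risks)
        ens_risk = float(cv_risks[int(np.argmax(weights))])
    else:
        if family == "gaussian":
            weights = fit_meta_nnls(Z, y, solver=solver)
        else:
            weights = _fit_meta_nll(Z, y, solver=solver)
        ens_risk = _risk(Z @ weights, y, family)

    fitted = [fit_learner(spec, X, y, seed=seed + 31 * l)
              for l, spec in zip(kept, kept_specs)]
    return SuperLearnerFit(library=kept_specs, folds=folds, cv_risks=cv_risks,
                           meta=meta, weights=weights, family=family,
                           fitted_learners=fitted, cv_risk_ensemble=ens_risk)


# ---------------------------------------------------------------------------
# strategy facade used by the TMLE stage

class SingleLearner:
    """Strategy wrapper fitting one base learner on the full data."""

    def __init__(self, spec: LearnerSpec):
        self.spec = spec

    def fit(self, X, y, seed: int = 0):
        return fit_learner(self.spec, X, y, seed=seed)


class StackedLearner:
    """Strategy wrapper fitting a super learner."""

    def __init__(self, library: Sequence[LearnerSpec], V: int = 10,
                 meta: str = "nnls", solver: str = "nnls"):
        self.library = list(library)
        self.V = V
        self.meta = meta
        self.solver = solver

    def fit(self, X, y, seed: int = 0):
        return fit_super_learner(self.library, X, y, V=self.V, meta=self.meta,
                                 seed=seed, solver=self.solver)


def as_strategy(obj):
    """Normalise a LearnerSpec / strategy object to the ``fit`` protocol."""
    if isinstance(obj, LearnerSpec):
        return SingleLearner(obj)
    if hasattr(obj, "fit"):
        return obj
    raise LearnerError(f"cannot interpret {obj!r} as a learner strategy")
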