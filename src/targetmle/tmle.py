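"""Targeted maximum likelihood estimation of the average treatment effect.

The estimator follows the standard construction for a continuous outcome:

1.  Map the outcome onto [0, 1] with the affine transform
    ``y* = (y - a) / (b - a)``.
2.  Fit an initial outcome regression Q(A, W) for ``y*`` and predict the
    potential outcomes Q(1, W), Q(0, W).
3.  Fit the propensity score g(W) = P(A = 1 | W), truncated away from 0
    and 1 for positivity.
4.  Form the clever covariates H1 = A / g and H0 = (1 - A) / (1 - g) and
    estimate the fluctuation coefficients (eps1, eps2) by a no-intercept
    quasi-binomial regression of ``y*`` on (H1, H0) with offset
    ``logit Q(A, W)``.
5.  Update the potential-outcome predictions on the logit scale and read
    off ``psi = (b - a) * mean(Q*(1, W) - Q*(0, W))``.
6.  The standard error comes from the sample variance of the efficient
    influence curve; the 95% interval uses the 1.959964 normal quantile.

The fluctuation solves the efficient-influence-curve estimating equation,
which is what gives the estimator its double robustness: it is consistent
if either the outcome regression or the propensity model is correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import OUTCOME_COL, TREATMENT_COL, design_matrix, validate_cohort
from .learners import as_strategy

Z975 = 1.959964

DEFAULT_G_BOUNDS = (0.025, 0.975)
DEFAULT_Q_BOUNDS = (0.001, 0.999)


class TMLEError(RuntimeError):
    """Raised when a TMLE stage cannot be completed."""


class FluctuationError(TMLEError):
    """Fluctuation regression failed to converge; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class OutcomeBounds:
    """Affine bounds used to map the outcome onto [0, 1]."""

    a: float
    b: float

    def __post_init__(self):
        if not self.b > self.a:
            raise TMLEError(f"need b > a, got ({self.a}, {self.b})")

    @property
    def width(self) -> float:
        return self.b - self.a


@dataclass
class NuisanceEstimates:
    """Bounded-scale outcome predictions and truncated propensity scores."""

    Q_AW: np.ndarray
    Q_1W: np.ndarray
    Q_0W: np.ndarray
    g_W: np.ndarray
    g_bounds: tuple
    q_bounds: tuple
    n_truncated_g: int = 0
    n_truncated_q: int = 0


@dataclass
class FluctuationFit:
    """Clever covariates and fitted fluctuation coefficients."""

    H1: np.ndarray
    H0: np.ndarray
    eps: tuple
    mode: str
    trace: list


@dataclass
class ATEEstimate:
    """ATE on the original outcome scale with influence-curve inference."""

    psi: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    method_label: str = ""
    dataset_label: str = ""

    @classmethod
    def from_psi_se(cls, psi: float, se: float, n: int,
                    method_label: str = "", dataset_label: str = "") -> "ATEEstimate":
        return cls(psi=psi, se=se, ci_low=psi - Z975 * se, ci_high=psi + Z975 * se,
                   n=n, method_label=method_label, dataset_label=dataset_label)

    def format(self) -> str:
        """Render as ``psi se s.e [low,high]``."""
        return (f"{self.psi:.3f} {self.se:.3f} s.e "
                f"[{self.ci_low:.3f},{self.ci_high:.3f}]")

    @property
    def z(self) -> float:
        return self.psi / self.se


@dataclass
class TMLEDiagnostics:
    """Positivity and targeting diagnostics for one TMLE run."""

    g_histogram: tuple
    n_truncated_g: int
    n_truncated_q: int
    eps: tuple
    score_h1: float
    score_h0: float
    mean_eic: float


# ---------------------------------------------------------------------------
# stage operations

def bound_outcome(y, bounds: OutcomeBounds | None = None
                  ) -> tuple[np.ndarray, OutcomeBounds]:
    """Affine map of the outcome into [0, 1]; records bounds for inversion."""
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise TMLEError("outcome contains non-finite values")
    if bounds is None:
        a, b = float(y.min()), float(y.max())
        if a == b:
            raise TMLEError("constant outcome: bounds would collapse (b = a)")
        bounds = OutcomeBounds(a, b)
    else:
        if y.min() < bounds.a or y.max() > bounds.b:
            raise TMLEError("outcome values fall outside the supplied bounds")
    return (y - bounds.a) / bounds.width, bounds


def unbound_outcome(y_star, bounds: OutcomeBounds) -> np.ndarray:
    """Invert :func:`bound_outcome`."""
    return np.asarray(y_star, float) * bounds.width + bounds.a


def fit_initial_outcome(learner, W, A, y_star,
                        q_bounds: tuple = DEFAULT_Q_BOUNDS,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Initial outcome regression on the bounded scale.

    Returns (Q_AW, Q_1W, Q_0W, number of truncated predictions).  The
    learner sees the covariates plus treatment as inputs; predictions are
    made under observed A, A = 1 and A = 0 and truncated into ``q_bounds``.
    Gaussian-family learners are permitted (the outcome is continuous in
    [0, 1]); their out-of-range predictions are handled by the truncation.
    """
    W = np.atleast_2d(np.asarray(W, float))
    A = np.asarray(A, float)
    y_star = np.asarray(y_star, float)
    if y_star.min() < 0 or y_star.max() > 1:
        raise TMLEError("y_star must lie in [0,1]; run bound_outcome first")
    strategy = as_strategy(learner)
    X = np.column_stack([W, A])
    try:
        fit = strategy.fit(X, y_star, seed=seed)
    except Exception as exc:
        raise TMLEError(f"outcome-model fit failed: {exc}") from exc
    ones = np.ones_like(A)
    raw = [fit.predict(X),
           fit.predict(np.column_stack([W, ones])),
           fit.predict(np.column_stack([W, 0 * ones]))]
    lo, hi = q_bounds
    n_trunc = int(sum(((r < lo) | (r > hi)).sum() for r in raw))
    Q_AW, Q_1W, Q_0W = (np.clip(r, lo, hi) for r in raw)
    return Q_AW, Q_1W, Q_0W, n_trunc


def fit_propensity(learner, W, A, g_bounds: tuple = DEFAULT_G_BOUNDS,
                   seed: int = 0) -> tuple[np.ndarray, int]:
    """Propensity scores P(A = 1 | W), truncated into ``g_bounds``."""
    W = np.atleast_2d(np.asarray(W, float))
    A = np.asarray(A, float)
    if not set(np.unique(A)) <= {0.0, 1.0}:
        raise TMLEError("treatment must be binary 0/1")
    if len(np.unique(A)) < 2:
        raise TMLEError("only one treatment arm present: positivity is impossible")
    strategy = as_strategy(learner)
    try:
        fit = strategy.fit(W, A, seed=seed)
    except Exception as exc:
        raise TMLEError(f"propensity-model fit failed: {exc}") from exc
    raw = fit.predict(W)
    lo, hi = g_bounds
    n_trunc = int(((raw < lo) | (raw > hi)).sum())
    return np.clip(raw, lo, hi), n_trunc


def compute_clever_covariates(A, g_W) -> tuple[np.ndarray, np.ndarray]:
    """H1 = A / g and H0 = (1 - A) / (1 - g)."""
    A = np.asarray(A, float)
    g = np.asarray(g_W, float)
    if g.min() <= 0 or g.max() >= 1:
        raise TMLEError("propensity scores must lie strictly inside (0,1)")
    return A / g, (1 - A) / (1 - g)


def _newton_offset_logistic(y, offset, H, max_iter: int = 200,
                            tol: float = 1e-13) -> tuple[np.ndarray, list]:
    """Maximise the Bernoulli quasi-likelihood of a no-intercept offset
    logistic model by damped Newton iterations.

    Converges to mean-score components below ``tol`` — tighter than
    generic IRLS stopping rules, which matters because the efficient
    influence curve is centred only up to the residual score.
    """
    y = np.asarray(y, float)
    H = np.atleast_2d(np.asarray(H, float))
    if H.shape[0] != len(y):
        H = H.T
    n, k = H.shape
    eps = np.zeros(k)

    def loglik(e):
        mu = np.clip(expit(offset + H @ e), 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(mu * 0 + 1 - mu)))

    trace = []
    ll = loglik(eps)
    for it in range(max_iter):
        mu = expit(offset + H @ eps)
        score = H.T @ (y - mu) / n
        trace.append((it, eps.copy(), float(np.abs(score).max())))
        if np.abs(score).max() < tol:
            return eps, trace
        w = np.clip(mu * (1 - mu), 1e-12, None)
        hess = (H * w[:, None]).T @ H / n
        try:
            step = np.linalg.solve(hess + 1e-14 * np.eye(k), score)
        except np.linalg.LinAlgError as exc:
            raise FluctuationError(f"singular Hessian at iteration {it}",
                                   trace) from exc
        # halving line search on the quasi-likelihood
        scale = 1.0
        for _ in range(60):
            cand = eps + scale * step
            ll_cand = loglik(cand)
            if ll_cand >= ll - 1e-12:
                eps, ll = cand, ll_cand
                break
            scale *= 0.5
        else:
            raise FluctuationError("line search failed", trace)
    # accept near-machine-precision stalls
    mu = expit(offset + H @ eps)
    score = H.T @ (y - mu) / n
    if np.abs(score).max() < 1e-9:
        return eps, trace
    raise FluctuationError(
        f"fluctuation did not converge: max|score| = {np.abs(score).max():.3e}",
        trace)


def fit_fluctuation(y_star, Q_AW, H1, H0, mode: str = "two_eps") -> FluctuationFit:
    """Estimate the fluctuation coefficient(s) epsilon.

    ``two_eps``: separate coefficients on H1 and H0 (no intercept, offset
    ``logit Q(A, W)``).  ``one_eps``: a single coefficient on H1 - H0.
    """
    if mode not in ("two_eps", "one_eps"):
        raise TMLEError(f"unknown fluctuation mode {mode!r}")
    y_star = np.asarray(y_star, float)
    Q_AW = np.asarray(Q_AW, float)
    if Q_AW.min() <= 0 or Q_AW.max() >= 1:
        raise TMLEError("Q_AW must lie strictly inside (0,1)")
    H1 = np.asarray(H1, float)
    H0 = np.asarray(H0, float)
    offset = logit(Q_AW)
    if mode == "two_eps":
        H = np.column_stack([H1, H0])
    else:
        H = (H1 - H0)[:, None]
    eps, trace = _newton_offset_logistic(y_star, offset, H)
    return FluctuationFit(H1=H1, H0=H0, eps=tuple(float(e) for e in eps),
                          mode=mode, trace=trace)


def update_counterfactual_predictions(Q_1W, Q_0W, g_W, fit: FluctuationFit
                                      ) -> tuple[np.ndarray, np.ndarray]:
    """Targeted update of the potential-outcome predictions.

    The clever covariate evaluated at A = 1 is 1/g and at A = 0 is
    1/(1 - g) (two-coefficient mode) or -1/(1 - g) (single-coefficient
    mode).
    """
    Q_1W = np.asarray(Q_1W, float)
    Q_0W = np.asarray(Q_0W, float)
    g = np.asarray(g_W, float)
    if all(e == 0.0 for e in fit.eps):  # exact identity at zero fluctuation
        return Q_1W.copy(), Q_0W.copy()
    if fit.mode == "two_eps":
        e1, e0 = fit.eps
        Qs1 = expit(logit(Q_1W) + e1 / g)
        Qs0 = expit(logit(Q_0W) + e0 / (1 - g))
    else:
        (e,) = fit.eps
        Qs1 = expit(logit(Q_1W) + e / g)
        Qs0 = expit(logit(Q_0W) - e / (1 - g))
    # keep the open interval even where expit saturates in floating point
    tiny = 1e-12
    return np.clip(Qs1, tiny, 1 - tiny), np.clip(Qs0, tiny, 1 - tiny)


def estimate_ate(Qstar_1W, Qstar_0W, bounds: OutcomeBounds) -> float:
    """Rescale the targeted mean difference back to the outcome scale."""
    Qstar_1W = np.asarray(Qstar_1W, float)
    Qstar_0W = np.asarray(Qstar_0W, float)
    return float(bounds.width * np.mean(Qstar_1W - Qstar_0W))


def influence_curve(y_star, A, Qstar_AW, Qstar_1W, Qstar_0W, g_W,
                    psi_star: float) -> np.ndarray:
    """Per-row efficient influence curve on the bounded scale."""
    A = np.asarray(A, float)
    g = np.asarray(g_W, float)
    resid = np.asarray(y_star, float) - np.asarray(Qstar_AW, float)
    return ((A / g - (1 - A) / (1 - g)) * resid
            + np.asarray(Qstar_1W, float) - np.asarray(Qstar_0W, float)
            - psi_star)


def influence_curve_ci(y_star, A, Qstar_AW, Qstar_1W, Qstar_0W, g_W,
                       psi: float, bounds: OutcomeBounds,
                       method_label: str = "", dataset_label: str = ""
                       ) -> ATEEstimate:
    """95% interval from the sample variance of the influence curve."""
    n = len(np.asarray(y_star))
    if n < 2:
        raise TMLEError("need at least 2 rows for influence-curve inference")
    D = influence_curve(y_star, A, Qstar_AW, Qstar_1W, Qstar_0W, g_W,
                        psi / bounds.width)
    se = float(bounds.width * np.sqrt(np.var(D, ddof=1) / n))
    return ATEEstimate.from_psi_se(psi, se, n, method_label, dataset_label)


def g_computation(Q_1W, Q_0W, bounds: OutcomeBounds) -> float:
    """Plug-in ATE from the initial fit, without targeting."""
    return estimate_ate(Q_1W, Q_0W, bounds)


# ---------------------------------------------------------------------------
# end-to-end estimator

def tmle_ate(cohort: pd.DataFrame, outcome_learner, propensity_learner,
             mode: str = "two_eps",
             g_bounds: tuple = DEFAULT_G_BOUNDS,
             q_bounds: tuple = DEFAULT_Q_BOUNDS,
             outcome_bounds: OutcomeBounds | None = None,
             seed: int = 0,
             method_label: str = "", dataset_label: str = "",
             return_diagnostics: bool = False):
    """Full targeted estimate of the ATE from a complete cohort table.

    Composes bounding, initial fits, clever covariates, fluctuation,
    targeted update, rescaling and influence-curve inference.  Missingness
    anywhere in the analysis columns is an explicit error (impute or take
    complete cases first).
    """
    validate_cohort(cohort, require_complete=True)
    W, _ = design_matrix(cohort)
    A = cohort[TREATMENT_COL].to_numpy(float)
    y = cohort[OUTCOME_COL].to_numpy(float)

    y_star, bounds = bound_outcome(y, outcome_bounds)
    Q_AW, Q_1W, Q_0W, n_trunc_q = fit_initial_outcome(
        outcome_learner, W, A, y_star, q_bounds=q_bounds, seed=seed)
    g_W, n_trunc_g = fit_propensity(
        propensity_learner, W, A, g_bounds=g_bounds, seed=seed + 1)
    H1, H0 = compute_clever_covariates(A, g_W)
    fluct = fit_fluctuation(y_star, Q_AW, H1, H0, mode=mode)
    Qs1, Qs0 = update_counterfactual_predictions(Q_1W, Q_0W, g_W, fluct)
    Qstar_AW = np.where(A == 1, Qs1, Qs0)
    psi = estimate_ate(Qs1, Qs0, bounds)
    est = influence_curve_ci(y_star, A, Qstar_AW, Qs1, Qs0, g_W, psi, bounds,
                             method_label=method_label,
                             dataset_label=dataset_label)
    if not return_diagnostics:
        return est
    D = influence_curve(y_star, A, Qstar_AW, Qs1, Qs0, g_W, psi / bounds.width)
    hist = np.histogram(g_W, bins=10, range=(0.0, 1.0))
    diag = TMLEDiagnostics(
        g_histogram=(hist[0].tolist(), hist[1].tolist()),
        n_truncated_g=n_trunc_g, n_truncated_q=n_trunc_q,
        eps=fluct.eps,
        score_h1=float(np.mean(H1 * (y_star - Qstar_AW))),
        score_h0=float(np.mean(H0 * (y_star - Qstar_AW))),
        mean_eic=float(np.mean(D)))
    return est, diag
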