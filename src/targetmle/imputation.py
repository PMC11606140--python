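"""Chained-equations multiple imputation and Rubin pooling.

Continuous columns are imputed by predictive mean matching (PMM): an OLS
regression on the remaining analysis columns predicts the conditional
mean for every row, and each missing entry receives the observed value of
one of the ``donor_k`` rows whose predicted means are nearest, drawn
uniformly.  Binary columns are imputed by Bernoulli draws from a fitted
logistic regression, 3+ level categoricals by draws from a multinomial
logit (with a ridge fallback on separation).  The NLR ratio columns are
never modelled directly: the underlying neutrophil and lymphocyte counts
are imputed and the ratio recomputed passively after every sweep, removing
the circularity of imputing the outcome from itself.

Per-imputation ATE estimates can be combined with Rubin's rules; with a
single imputation the pooled result is the input estimate verbatim.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as student_t
from sklearn.linear_model import LogisticRegression

from .cohort import (
    ANALYSIS_COLS,
    BINARY_COLS,
    HIV_COL,
    HIV_LEVELS,
    NLR_PARENTS,
    TREATMENT_COL,
)
from .tmle import Z975, ATEEstimate


class ImputationError(RuntimeError):
    """Raised when the chained-equations engine cannot proceed."""


class EmptyCohortError(ImputationError):
    """Complete-case filtering removed every row."""


VALID_METHODS = ("pmm", "logistic", "polytomous", "passive")


@dataclass
class ImputationSpec:
    """Chained-equations settings.

    ``method_map`` overrides the per-column model choice; by default
    continuous columns get PMM, binary columns logistic regression,
    3+ level categoricals polytomous regression, and NLR columns passive
    recomputation from their counts.
    """

    m: int = 20
    maxit: int = 10
    donor_k: int = 5
    method_map: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ImputationError(f"m must be >= 1, got {self.m}")
        if self.maxit < 1:
            raise ImputationError(f"maxit must be >= 1, got {self.maxit}")
        if self.donor_k < 1:
            raise ImputationError(f"donor_k must be >= 1, got {self.donor_k}")
        for col, meth in self.method_map.items():
            if not any(meth.startswith(v) for v in VALID_METHODS):
                raise ImputationError(f"unknown method {meth!r} for column {col!r}")


@dataclass
class CompletedCohortSet:
    """m completed cohort tables plus provenance."""

    imputations: list
    spec: ImputationSpec
    source_fingerprint: int

    def __len__(self) -> int:
        return len(self.imputations)


@dataclass
class PooledEstimate:
    """Rubin-pooled ATE across imputations."""

    psi_bar: float
    total_var: float
    ci_low: float
    ci_high: float
    m: int
    within_var: float
    between_var: float
    df: float

    def to_ate_estimate(self, n: int, method_label: str = "",
                        dataset_label: str = "") -> ATEEstimate:
        return ATEEstimate(psi=self.psi_bar, se=float(np.sqrt(self.total_var)),
                           ci_low=self.ci_low, ci_high=self.ci_high, n=n,
                           method_label=method_label, dataset_label=dataset_label)


def complete_case_filter(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows with no missing value in any analysis column, order preserved.

    Columns outside the analysis scope (e.g. the raw cell counts) do not
    cause a row to drop.
    """
    keep = cohort[ANALYSIS_COLS].notna().all(axis=1)
    if not keep.any():
        raise EmptyCohortError("complete-case filtering removed every row")
    return cohort.loc[keep].copy()


# ---------------------------------------------------------------------------
# chained-equations engine

def _default_method(col: str, have_counts: dict) -> Optional[str]:
    if col in NLR_PARENTS and have_counts[col]:
        return "passive"
    if col in BINARY_COLS or col == TREATMENT_COL:
        return "logistic"
    if col == HIV_COL:
        return "polytomous"
    return "pmm"


def _encode_predictors(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    """Numeric design matrix from the current (filled) predictor columns."""
    parts = [np.ones(len(df))]
    for c in cols:
        if c == HIV_COL:
            hiv = df[c].astype(str)
            parts.append((hiv == "yes").to_numpy(float))
            parts.append((hiv == "unknown").to_numpy(float))
        else:
            parts.append(df[c].to_numpy(float))
    return np.column_stack(parts)


def _pmm_impute(X: np.ndarray, y: np.ndarray, obs: np.ndarray, mis: np.ndarray,
                donor_k: int, rng: np.random.Generator) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    pred = X @ beta
    pred_obs = pred[obs]
    y_obs = y[obs]
    k = min(donor_k, len(y_obs))
    out = np.empty(mis.sum())
    for j, p in enumerate(pred[mis]):
        d = np.abs(pred_obs - p)
        donors = np.argpartition(d, k - 1)[:k] if k < len(d) else np.arange(len(d))
        out[j] = y_obs[donors[rng.integers(len(donors))]]
    return out


def _logistic_impute(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                     mis: np.ndarray, rng: np.random.Generator,
                     col: str, sweep: int) -> np.ndarray:
    y_obs = y[obs]
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(mis.sum(), classes[0])
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y_obs, X[obs], family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
            beta = np.asarray(res.params, float)
            if not np.all(np.isfinite(beta)):
                raise ValueError
        except Exception:
            try:
                res = sm.GLM(y_obs, X[obs],
                             family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-4, L1_wt=0.0, maxiter=300)
                beta = np.asarray(res.params, float)
            except Exception as exc:
                raise ImputationError(
                    f"logistic imputation model failed for column {col!r} "
                    f"at sweep {sweep}") from exc
    p = expit(X[mis] @ beta)
    return (rng.random(mis.sum()) < p).astype(float)


def _polytomous_impute(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                       mis: np.ndarray, rng: np.random.Generator,
                       col: str, sweep: int) -> np.ndarray:
    y_obs = y[obs]
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(mis.sum(), classes[0], dtype=object)
    # small ridge stabilises separation in thin strata; stronger fallback
    for C in (1e4, 1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LogisticRegression(C=C, max_iter=2000)
                model.fit(X[obs], y_obs)
            probs = model.predict_proba(X[mis])
            break
        except Exception:
            continue
    else:
        raise ImputationError(
            f"polytomous imputation model failed for column {col!r} at sweep {sweep}")
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cum))
    picks = (u[:, None] > cum).sum(axis=1)
    return model.classes_[np.clip(picks, 0, len(model.classes_) - 1)]


def _recompute_passive(df: pd.DataFrame, orig_missing: pd.DataFrame) -> None:
    """Enforce nlr = neut / lymph for rows touched by imputation."""
    for ratio_col, (ncol, lcol) in NLR_PARENTS.items():
        if ncol not in df.columns or lcol not in df.columns:
            continue
        # observed ratio + imputed counts: back-solve neutrophils so the
        # identity holds without disturbing the observed value
        back = (~orig_missing[ratio_col]) & (orig_missing[ncol] | orig_missing[lcol])
        if back.any():
            df.loc[back, ncol] = df.loc[back, ratio_col] * df.loc[back, lcol]
        # imputed ratio: recompute from the (possibly imputed) counts
        fwd = orig_missing[ratio_col]
        if fwd.any():
            df.loc[fwd, ratio_col] = df.loc[fwd, ncol] / df.loc[fwd, lcol]


def fit_chained_imputation(cohort: pd.DataFrame, spec: ImputationSpec
                           ) -> CompletedCohortSet:
    """Run chained-equations imputation; deterministic given ``spec.seed``.

    Columns are visited in increasing order of missingness count; passive
    ratio columns are recomputed after every sweep.  The treatment column
    must be complete and is never modified.
    """
    spec.validate()
    if cohort[TREATMENT_COL].isna().any():
        raise ImputationError("treatment column must be complete before imputation")
    df0 = cohort.copy()
    have_counts = {r: all(c in df0.columns for c in p)
                   for r, p in NLR_PARENTS.items()}
    work_cols = [c for c in df0.columns if c != TREATMENT_COL]
    orig_missing = df0[df0.columns].isna()

    methods: dict[str, str] = {}
    for col in work_cols:
        if not orig_missing[col].any():
            continue
        meth = spec.method_map.get(col) or _default_method(col, have_counts)
        methods[col] = meth
        if meth != "passive" and (~orig_missing[col]).sum() == 0:
            raise ImputationError(f"column {col!r} has zero observed values")
        if meth == "pmm" and (~orig_missing[col]).sum() < spec.donor_k:
            raise ImputationError(
                f"column {col!r} has fewer observed values than donor_k")

    model_cols = [c for c, m in methods.items() if m != "passive"]
    # ascending missingness stabilises the chained equations
    model_cols.sort(key=lambda c: (int(orig_missing[c].sum()), c))

    fingerprint = int(pd.util.hash_pandas_object(
        df0.fillna(-999.25).astype(str)).sum() % (2 ** 63))
    completed = []
    for i in range(spec.m):
        rng = np.random.default_rng([spec.seed, i])
        df = df0.copy()
        # initial fill: random draws from the observed values of each column
        for col in model_cols:
            mis = orig_missing[col]
            obs_vals = df.loc[~mis, col].to_numpy()
            df.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()))
        _recompute_passive(df, orig_missing)

        for sweep in range(1, spec.maxit + 1):
            for col in model_cols:
                mis = orig_missing[col].to_numpy()
                obs = ~mis
                predictors = [c for c in ANALYSIS_COLS if c != col]
                # counts as targets: drop their own derived ratio (circularity)
                for ratio_col, parents in NLR_PARENTS.items():
                    if col in parents and ratio_col in predictors:
                        predictors.remove(ratio_col)
                X = _encode_predictors(df, predictors)
                meth = methods[col]
                if meth == "pmm":
                    y = df[col].to_numpy(float)
                    df.loc[mis, col] = _pmm_impute(X, y, obs, mis,
                                                   spec.donor_k, rng)
                elif meth == "logistic":
                    y = df[col].to_numpy(float)
                    df.loc[mis, col] = _logistic_impute(X, y, obs, mis, rng,
                                                        col, sweep)
                elif meth == "polytomous":
                    y = df[col].to_numpy(object)
                    df.loc[mis, col] = _polytomous_impute(X, y, obs, mis, rng,
                                                          col, sweep)
                else:
                    raise ImputationError(f"unexpected method {meth!r}")
            _recompute_passive(df, orig_missing)
        completed.append(df)
    return CompletedCohortSet(imputations=completed, spec=spec,
                              source_fingerprint=fingerprint)


# ---------------------------------------------------------------------------
# pooling

def pool_rubin(estimates: Sequence[ATEEstimate]) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    ``psi_bar`` is the mean point estimate; the total variance is the mean
    squared standard error plus ``(1 + 1/m)`` times the between-imputation
    variance.  The interval uses Rubin's small-sample degrees of freedom
    (normal quantile when the between-imputation variance vanishes).  A
    single estimate is returned unchanged.
    """
    estimates = list(estimates)
    if not estimates:
        raise ImputationError("no estimates to pool")
    labels = {(e.method_label, e.dataset_label) for e in estimates}
    if len(labels) > 1:
        raise ImputationError(f"refusing to pool mixed estimates: {sorted(labels)}")
    m = len(estimates)
    if m == 1:
        e = estimates[0]
        return PooledEstimate(psi_bar=e.psi, total_var=e.se ** 2,
                              ci_low=e.ci_low, ci_high=e.ci_high, m=1,
                              within_var=e.se ** 2, between_var=0.0,
                              df=np.inf)
    points = np.array([e.psi for e in estimates])
    within = float(np.mean([e.se ** 2 for e in estimates]))
    between = float(np.var(points, ddof=1))
    total = within + (1 + 1 / m) * between
    psi_bar = float(points.mean())
    se = float(np.sqrt(total))
    if between == 0.0:
        df = np.inf
        q = Z975
    else:
        df = (m - 1) * (1 + within / ((1 + 1 / m) * between)) ** 2
        q = float(student_t.ppf(0.975, df))
    return PooledEstimate(psi_bar=psi_bar, total_var=total,
                          ci_low=psi_bar - q * se, ci_high=psi_bar + q * se,
                          m=m, within_var=within, between_var=between, df=df)
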