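"""Synthetic ICU cohort generator with a known true average treatment effect.

The generator emulates the statistical shape of an observational
corticosteroid cohort: confounded treatment assignment (baseline NLR and
co-morbidities shift the odds of receiving dexamethasone), a strictly
positive continuous day-5 NLR outcome built from covariates, treatment and
noise, and neutrophil / lymphocyte counts underlying every NLR so that
passive imputation of the ratio has a substrate.  Missingness is injected
separately with configurable per-column rates (MCAR, or MAR conditioning on
a fully observed binary column).

Ground truth
------------
With the default additive outcome model the conditional mean of the day-5
NLR is ``intercept + beta' x + tau * A``, so the true average treatment
effect is exactly ``tau``.  Noise is Gaussian truncated *symmetrically*
per row at ``±(mu_i - noise_floor)``: the symmetric truncation keeps the
conditional mean equal to the linear predictor (hence the closed-form
truth) while guaranteeing positive outcomes.  A multiplicative log-scale
model is available for sensitivity work; its true effect is obtained by
Monte Carlo over the covariate distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import (
    ALL_COLS,
    BINARY_COLS,
    HIV_COL,
    HIV_LEVELS,
    NLR_PARENTS,
    TREATMENT_COL,
    validate_cohort,
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


class MissingnessError(ValueError):
    """Invalid missingness request (e.g. masking the treatment column)."""


# marginal prevalences of the binary covariates (probability of 1)
DEFAULT_PREVALENCE: Mapping[str, float] = {
    "gender": 0.56,          # 1 = female
    "ventilation": 0.18,     # 1 = invasive
    "hypertension": 0.65,
    "hyperlipidaemia": 0.12,
    "diabetes": 0.57,
    "ckd": 0.08,
    "asthma": 0.04,
}

DEFAULT_HIV_PROBS = (0.79, 0.12, 0.09)  # no / yes / unknown

# treatment-assignment log-odds; features: binary covariates as-is,
# age_c = (age - 56) / 10, nlr_d1_c = nlr_d1 - 12.6, hiv dummies
DEFAULT_TREAT_COEFS: Mapping[str, float] = {
    "nlr_d1_c": 0.04,
    "ventilation": -0.30,
    "diabetes": -0.20,
    "age_c": 0.05,
}

# outcome mean model on the NLR scale; nlr_d1 enters untransformed
DEFAULT_OUT_COEFS: Mapping[str, float] = {
    "nlr_d1": 0.85,
    "ventilation": 1.50,
    "diabetes": 0.80,
    "age_c": 0.50,
    "hypertension": 0.40,
}

# log-scale (mean, sd) for the lognormal cell counts, units 10^9 cells/L
DEFAULT_CELL_COUNT_PARAMS: Mapping[str, tuple[float, float]] = {
    "neut_d1": (np.log(10.0), 0.45),
    "lymph_d1": (np.log(0.8), 0.40),
    "lymph_d5": (np.log(0.7), 0.35),
}

_TREAT_FEATURES = BINARY_COLS + ["hiv_yes", "hiv_unknown", "age_c", "nlr_d1_c"]
_OUT_FEATURES = BINARY_COLS + ["hiv_yes", "hiv_unknown", "age_c", "nlr_d1"]

_AGE_CENTER = 56.0
_NLR_CENTER = 12.6


@dataclass
class MissingnessSpec:
    """Per-column missingness probabilities and mechanism.

    ``rates`` maps column names to probabilities in [0, 1).  Masking an NLR
    column also masks that day's counts (one Bernoulli event per row per
    day), and a count column may not be given a rate alongside its ratio.
    Under ``mechanism="mar"`` the configured rate applies where
    ``condition_on == 1`` and ``rate * mar_ratio`` elsewhere, so stated
    rates are upper bounds per stratum.
    """

    rates: Mapping[str, float] = field(default_factory=dict)
    mechanism: str = "mcar"
    condition_on: str = "ventilation"
    mar_ratio: float = 0.4

    def validate(self) -> None:
        if self.mechanism not in ("mcar", "mar"):
            raise MissingnessError(f"unknown mechanism {self.mechanism!r}")
        if TREATMENT_COL in self.rates:
            raise MissingnessError("treatment may not be masked (rows without "
                                   "treatment are dropped, not imputed)")
        for col, p in self.rates.items():
            if not (0.0 <= p < 1.0):
                raise MissingnessError(f"rate for {col!r} must be in [0,1), got {p}")
        for ratio_col, parents in NLR_PARENTS.items():
            if ratio_col in self.rates and any(c in self.rates for c in parents):
                raise MissingnessError(
                    f"specify a rate for {ratio_col!r} or its counts, not both")
        if self.mechanism == "mar":
            if not (0.0 <= self.mar_ratio <= 1.0):
                raise MissingnessError("mar_ratio must be in [0,1]")
            if self.condition_on in self.rates:
                raise MissingnessError("the MAR conditioning column must stay "
                                       "fully observed")


def default_missingness() -> MissingnessSpec:
    """Missingness profile used by the study runner when none is given.

    Outcome missingness is kept below 10%; a handful of covariates carry
    moderate missingness so chained imputation has real work to do.
    """
    return MissingnessSpec(
        rates={
            "nlr_d5": 0.08,
            "nlr_d1": 0.05,
            "age": 0.03,
            "hypertension": 0.05,
            "hiv": 0.05,
            "diabetes": 0.04,
        },
        mechanism="mcar",
    )


@dataclass
class SimulationConfig:
    """Data-generating parameters for the synthetic cohort.

    Coefficients are keyed by feature name; any feature not named gets 0.
    ``tau`` is the additive treatment effect in NLR units; ``tau_x_nlr``
    adds a treatment-by-baseline-NLR interaction (NLR units per unit of
    centred baseline NLR) for non-additive scenarios.
    """

    n: int = 168
    # calibrated so roughly three in four receive dexamethasone under the
    # default covariate mix (pure intercept-only models hit the value exactly)
    treat_intercept: float = 1.30
    treat_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREAT_COEFS))
    out_intercept: float = 4.0
    out_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUT_COEFS))
    tau: float = 2.0
    tau_x_nlr: float = 0.0
    sigma: float = 2.5
    cell_count_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CELL_COUNT_PARAMS))
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    hiv_probs: tuple[float, float, float] = DEFAULT_HIV_PROBS
    outcome_scale: str = "additive"  # or "log"
    noise_floor: float = 0.05
    miss_spec: Optional[MissingnessSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigurationError(f"n must be >= 2, got {self.n}")
        if not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if self.outcome_scale not in ("additive", "log"):
            raise ConfigurationError(
                f"outcome_scale must be 'additive' or 'log', got {self.outcome_scale!r}")
        if not self.noise_floor > 0:
            raise ConfigurationError("noise_floor must be > 0")
        for name, (mu, sd) in self.cell_count_params.items():
            if not sd > 0:
                raise ConfigurationError(f"cell_count_params[{name!r}] sd must be > 0")
            if not np.isfinite(mu):
                raise ConfigurationError(f"cell_count_params[{name!r}] log-mean not finite")
        for name, p in self.prevalence.items():
            if not (0.0 < p < 1.0):
                raise ConfigurationError(f"prevalence[{name!r}] must be in (0,1)")
        probs = np.asarray(self.hiv_probs, float)
        if probs.shape != (3,) or (probs <= 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError("hiv_probs must be 3 positive values summing to 1")
        known = set(_TREAT_FEATURES)
        bad = set(self.treat_coefs) - known
        if bad:
            raise ConfigurationError(f"treat_coefs has unknown features: {sorted(bad)}")
        bad = set(self.out_coefs) - set(_OUT_FEATURES)
        if bad:
            raise ConfigurationError(f"out_coefs has unknown features: {sorted(bad)}")
        if self.miss_spec is not None:
            self.miss_spec.validate()

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(mapping) - known
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")
        kwargs = dict(mapping)
        if "miss_spec" in kwargs and isinstance(kwargs["miss_spec"], Mapping):
            kwargs["miss_spec"] = MissingnessSpec(**kwargs["miss_spec"])
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Ground truth attached to a generated cohort."""

    true_ate: float
    config: SimulationConfig


def _feature_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Derived model features used by the treatment and outcome models."""
    hiv = df[HIV_COL].astype(str)
    feats = pd.DataFrame(index=df.index)
    for c in BINARY_COLS:
        feats[c] = df[c].astype(float)
    feats["hiv_yes"] = (hiv == "yes").astype(float)
    feats["hiv_unknown"] = (hiv == "unknown").astype(float)
    feats["age_c"] = (df["age"] - _AGE_CENTER) / 10.0
    feats["nlr_d1"] = df["nlr_d1"].astype(float)
    feats["nlr_d1_c"] = feats["nlr_d1"] - _NLR_CENTER
    return feats


def _linear(feats: pd.DataFrame, intercept: float, coefs: Mapping[str, float]) -> np.ndarray:
    eta = np.full(len(feats), float(intercept))
    for name, c in coefs.items():
        eta += float(c) * feats[name].to_numpy()
    return eta


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    df = pd.DataFrame(index=np.arange(n))
    df["age"] = np.clip(rng.normal(56.0, 11.0, n), 18.0, 95.0).round(1)
    for c in BINARY_COLS:
        df[c] = rng.binomial(1, config.prevalence[c], n)
    df[HIV_COL] = rng.choice(HIV_LEVELS, size=n, p=np.asarray(config.hiv_probs, float))
    mu_n, sd_n = config.cell_count_params["neut_d1"]
    mu_l, sd_l = config.cell_count_params["lymph_d1"]
    df["neut_d1"] = rng.lognormal(mu_n, sd_n, n)
    df["lymph_d1"] = rng.lognormal(mu_l, sd_l, n)
    df["nlr_d1"] = df["neut_d1"] / df["lymph_d1"]
    return df


def _outcome_mean(config: SimulationConfig, feats: pd.DataFrame, a: np.ndarray) -> np.ndarray:
    eta = _linear(feats, config.out_intercept, config.out_coefs)
    eta = eta + config.tau * a + config.tau_x_nlr * a * feats["nlr_d1_c"].to_numpy()
    return eta


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a complete (no-missingness) cohort of ``config.n`` rows.

    Deterministic given ``config.seed``.  Day-5 counts are back-solved from
    the simulated NLR (lymphocytes drawn, neutrophils = NLR x lymphocytes)
    so the passive ratio identity holds by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    df = _draw_covariates(config, rng)
    feats = _feature_frame(df)

    p_treat = expit(_linear(feats, config.treat_intercept, config.treat_coefs))
    a = rng.binomial(1, p_treat)
    df[TREATMENT_COL] = a

    if config.outcome_scale == "additive":
        mu = _outcome_mean(config, feats, a)
        half_width = mu - config.noise_floor
        if (half_width <= 0).any():
            raise ConfigurationError(
                "out_coefs/out_intercept/tau yield a non-positive conditional "
                "outcome mean; the additive model requires mu > noise_floor "
                "for every row")
        c = half_width / config.sigma
        noise = truncnorm.rvs(-c, c, loc=0.0, scale=config.sigma,
                              size=config.n, random_state=rng)
        y = mu + noise
    else:  # multiplicative on the log scale
        log_mu = np.log(np.maximum(_outcome_mean(config, feats, a), config.noise_floor))
        y = np.exp(log_mu + rng.normal(0.0, config.sigma, config.n))

    mu_l5, sd_l5 = config.cell_count_params["lymph_d5"]
    df["lymph_d5"] = rng.lognormal(mu_l5, sd_l5, config.n)
    df["neut_d5"] = y * df["lymph_d5"]
    # store the ratio as the literal division so passivity is bitwise exact
    df["nlr_d5"] = df["neut_d5"] / df["lymph_d5"]
    df = df[ALL_COLS]
    validate_cohort(df)

    if config.outcome_scale == "additive" and config.tau_x_nlr == 0.0:
        truth_val = float(config.tau)
    else:
        truth_val = true_ate(config, n_mc=200_000, seed=config.seed + 1)
    truth = SimulationTruth(true_ate=truth_val, config=config)

    if config.miss_spec is not None and config.miss_spec.rates:
        df = inject_missingness(df, config.miss_spec, seed=config.seed + 7)
    return df, truth


def true_ate(config: SimulationConfig, n_mc: int = 100_000, seed: int = 12345) -> float:
    """True E[Y(1) - Y(0)] under ``config``.

    For the additive model without treatment-covariate interaction the
    answer is ``tau`` exactly (no simulation).  Otherwise the expectation is
    taken by Monte Carlo over the covariate distribution; within each draw
    the conditional means under A=1 and A=0 are closed-form, so no outcome
    noise is simulated.
    """
    config.validate()
    if config.outcome_scale == "additive" and config.tau_x_nlr == 0.0:
        return float(config.tau)
    if n_mc < 10_000:
        raise ConfigurationError(f"n_mc must be >= 10000, got {n_mc}")
    mc = dataclasses.replace(config, n=n_mc, miss_spec=None)
    rng = np.random.default_rng(seed)
    df = _draw_covariates(mc, rng)
    feats = _feature_frame(df)
    ones = np.ones(n_mc)
    if config.outcome_scale == "additive":
        diff = _outcome_mean(mc, feats, ones) - _outcome_mean(mc, feats, 0 * ones)
    else:
        adj = np.exp(config.sigma ** 2 / 2.0)  # lognormal noise mean
        m1 = np.maximum(_outcome_mean(mc, feats, ones), config.noise_floor)
        m0 = np.maximum(_outcome_mean(mc, feats, 0 * ones), config.noise_floor)
        diff = adj * (m1 - m0)
    return float(diff.mean())


def inject_missingness(cohort: pd.DataFrame, miss_spec: MissingnessSpec,
                       seed: int = 0) -> pd.DataFrame:
    """Mask values per the missingness spec; reproducible given ``seed``.

    The treatment column is never masked.  Masking ``nlr_dX`` masks that
    day's neutrophil and lymphocyte counts in the same rows; masking a
    count column masks that day's derived ratio so the passive identity
    stays intact.
    """
    miss_spec.validate()
    unknown = [c for c in miss_spec.rates if c not in cohort.columns]
    if unknown:
        raise MissingnessError(f"rates name absent columns: {unknown}")
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    n = len(df)

    def row_probs(rate: float) -> np.ndarray:
        if miss_spec.mechanism == "mcar":
            return np.full(n, rate)
        strat = df[miss_spec.condition_on].to_numpy(float)
        if np.isnan(strat).any():
            raise MissingnessError(
                f"MAR conditioning column {miss_spec.condition_on!r} has missing values")
        return np.where(strat == 1, rate, rate * miss_spec.mar_ratio)

    for col, rate in miss_spec.rates.items():
        if rate == 0.0:
            continue
        mask = rng.random(n) < row_probs(rate)
        targets = [col]
        if col in NLR_PARENTS:  # ratio masked -> counts masked too
            targets += [c for c in NLR_PARENTS[col] if c in df.columns]
        else:
            for ratio_col, parents in NLR_PARENTS.items():
                if col in parents and ratio_col in df.columns:
                    targets.append(ratio_col)
        for t in targets:
            if df[t].dtype == object or str(df[t].dtype).startswith("string"):
                df.loc[mask, t] = np.nan
            else:
                df[t] = df[t].astype(float)
                df.loc[mask, t] = np.nan
    return df
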