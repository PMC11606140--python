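"""Patient-cohort table schema, validation and CSV round-trip.

The analysis operates on a flat table of ICU admissions.  Each row carries
baseline covariates W (age, gender, ventilation status and co-morbidities),
a binary corticosteroid indicator ``treatment`` (1 = dexamethasone,
0 = hydrocortisone) and the day-5 neutrophil-lymphocyte ratio (NLR) as the
continuous outcome.  NLR columns are derived ratios: whenever both cell
counts of a day are present, ``nlr = neut / lymph`` must hold to within
:data:`RATIO_RTOL`.  Any column may contain missing values except
``treatment`` (rows without a treatment are outside the analysis contract
and must be dropped before entry).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: binary 0/1 covariates
BINARY_COLS = [
    "gender",
    "ventilation",
    "hypertension",
    "hyperlipidaemia",
    "diabetes",
    "ckd",
    "asthma",
]

#: 3-level HIV status (the "unknown" level is a first-class category)
HIV_COL = "hiv"
HIV_LEVELS = ["no", "yes", "unknown"]

CONTINUOUS_COLS = ["age", "nlr_d1", "nlr_d5"]
COUNT_COLS = ["neut_d1", "lymph_d1", "neut_d5", "lymph_d5"]
TREATMENT_COL = "treatment"
OUTCOME_COL = "nlr_d5"

#: columns entering the causal analysis (complete-case scope)
ANALYSIS_COLS = ["age"] + BINARY_COLS + [HIV_COL, "nlr_d1", "nlr_d5", TREATMENT_COL]

#: all columns a generated cohort carries, in canonical order
ALL_COLS = (
    ["age"]
    + BINARY_COLS
    + [HIV_COL]
    + COUNT_COLS
    + ["nlr_d1", "nlr_d5", TREATMENT_COL]
)

#: relative tolerance for the passive ratio identity nlr == neut / lymph
RATIO_RTOL = 1e-12

#: day -> (neutrophil column, lymphocyte column, ratio column)
NLR_PARENTS = {
    "nlr_d1": ("neut_d1", "lymph_d1"),
    "nlr_d5": ("neut_d5", "lymph_d5"),
}


class CohortError(ValueError):
    """Raised when a cohort table violates the schema contract."""


def validate_cohort(df: pd.DataFrame, require_complete: bool = False) -> None:
    """Check schema invariants; raise :class:`CohortError` on violation.

    Parameters
    ----------
    df : DataFrame with at least the analysis columns.
    require_complete : if True, any missing analysis value is an error
        (the TMLE stages operate on complete data only).
    """
    missing_cols = [c for c in ANALYSIS_COLS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort lacks required columns: {missing_cols}")
    a = df[TREATMENT_COL]
    if a.isna().any():
        raise CohortError("treatment column contains missing values; drop such rows")
    if not np.isin(a.to_numpy(), [0, 1]).all():
        raise CohortError("treatment must be coded 0 (hydrocortisone) / 1 (dexamethasone)")
    for col in ("nlr_d1", "nlr_d5"):
        vals = df[col].dropna()
        if (vals <= 0).any():
            raise CohortError(f"{col} contains non-positive values")
    hiv = df[HIV_COL].dropna()
    bad = set(hiv.unique()) - set(HIV_LEVELS)
    if bad:
        raise CohortError(f"unexpected hiv levels: {sorted(bad)}")
    for ratio_col, (ncol, lcol) in NLR_PARENTS.items():
        if ncol in df.columns and lcol in df.columns:
            both = df[ncol].notna() & df[lcol].notna() & df[ratio_col].notna()
            if both.any():
                expected = df.loc[both, ncol] / df.loc[both, lcol]
                actual = df.loc[both, ratio_col]
                rel = np.abs(actual - expected) / np.abs(expected)
                if (rel > RATIO_RTOL).any():
                    raise CohortError(f"{ratio_col} inconsistent with {ncol}/{lcol}")
    if require_complete:
        incomplete = df[ANALYSIS_COLS].isna().any(axis=1)
        if incomplete.any():
            raise CohortError(
                f"{int(incomplete.sum())} rows have missing analysis values; "
                "the targeting step does not accept missingness — run "
                "complete_case_filter or fit_chained_imputation first"
            )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={HIV_COL: "string"})
    df[HIV_COL] = df[HIV_COL].astype(object).where(df[HIV_COL].notna(), np.nan)
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with missing values encoded as empty fields."""
    df.to_csv(path, index=False, na_rep="")


def design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Covariate matrix W for the nuisance models.

    All baseline covariates plus the baseline NLR; the 3-level HIV status
    enters as two dummies against the ``no`` reference.  The outcome and
    treatment columns are excluded.
    """
    validate_cohort(df, require_complete=True)
    cols = {}
    cols["age"] = df["age"].to_numpy(float)
    for c in BINARY_COLS:
        cols[c] = df[c].to_numpy(float)
    hiv = df[HIV_COL].astype(str)
    cols["hiv_yes"] = (hiv == "yes").to_numpy(float)
    cols["hiv_unknown"] = (hiv == "unknown").to_numpy(float)
    cols["nlr_d1"] = df["nlr_d1"].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names
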