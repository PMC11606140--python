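"""End-to-end study runner.

Builds dataset variants from one cohort (multiply imputed, complete-case,
and an explicit ``naive-fill`` median/mode variant), runs each requested
TMLE method on each variant, and assembles a Table-2-style estimation grid
plus Table-1-style descriptive summaries and a forest-table export with a
pairwise confidence-interval overlap matrix.

Methods
-------
``par``      quasi-binomial GLMs for both nuisance models (parametric TMLE)
``sl-dsl``   super learner with the discrete (winner-take-all) meta-learner
``sl-nnls``  super learner with the convex simplex-weighted meta-learner
``tree``     gradient-boosted tree ensemble for both nuisance models
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ANALYSIS_COLS,
    BINARY_COLS,
    HIV_COL,
    HIV_LEVELS,
    NLR_PARENTS,
    TREATMENT_COL,
    read_cohort,
)
from .imputation import (
    ImputationSpec,
    complete_case_filter,
    fit_chained_imputation,
    pool_rubin,
)
from .learners import LearnerSpec, SingleLearner, StackedLearner, default_library
from .simulate import MissingnessSpec, SimulationConfig, generate_cohort
from .stats import chi_square_p, expected_counts, fisher_exact_rxc, rank_sum_p
from .tmle import ATEEstimate, tmle_ate

METHODS = ("par", "sl-dsl", "sl-nnls", "tree")
DATASETS = ("imputed", "complete-case", "naive-fill")

ARM_NAMES = {0: "hydrocortisone", 1: "dexamethasone"}


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# descriptive table

CATEGORICAL_VARS = {c: [0, 1] for c in BINARY_COLS} | {HIV_COL: HIV_LEVELS}
CONTINUOUS_VARS = ["age", "nlr_d1", "nlr_d5"]


@dataclass
class DescriptiveTable:
    """Cohort-characteristics summary by treatment arm."""

    rows: pd.DataFrame
    tests: pd.DataFrame

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows


def descriptive_table(cohort: pd.DataFrame,
                      expected_min: float = 5.0) -> DescriptiveTable:
    """Table-1-style summary with between-arm comparison tests.

    Categorical variables get level counts and within-arm column
    percentages; the comparison is a Pearson chi-square test for 2 x 2
    tables with all expected counts >= ``expected_min`` and Fisher's exact
    test otherwise.  Continuous variables get median [IQR] per arm and a
    Wilcoxon rank-sum p-value.  Missing values are excluded per variable.
    """
    a = cohort[TREATMENT_COL].to_numpy(float)
    arm_n = {arm: int((a == arm).sum()) for arm in (0, 1)}
    if arm_n[0] == 0 or arm_n[1] == 0:
        raise PipelineError("one treatment arm is empty")

    rows, tests = [], []
    # treatment split itself
    total = len(cohort)
    for arm in (0, 1):
        rows.append({"variable": "treatment", "level": ARM_NAMES[arm],
                     "n_hydrocortisone": arm_n[0] if arm == 0 else 0,
                     "n_dexamethasone": arm_n[1] if arm == 1 else 0,
                     "n_overall": arm_n[arm],
                     "pct_overall": 100.0 * arm_n[arm] / total})

    for var, levels in CATEGORICAL_VARS.items():
        sub = cohort[[var, TREATMENT_COL]].dropna()
        table = np.zeros((2, len(levels)), dtype=int)
        for i, arm in enumerate((0, 1)):
            for j, lev in enumerate(levels):
                table[i, j] = int(((sub[TREATMENT_COL] == arm)
                                   & (sub[var] == lev)).sum())
        arm_tot = table.sum(axis=1)
        overall = table.sum(axis=0)
        use_chi = (table.shape == (2, 2)
                   and (expected_counts(table) >= expected_min).all())
        if use_chi:
            test_name, p = "Pearson chi-square", chi_square_p(table)
        else:
            test_name, p = "Fisher exact", fisher_exact_rxc(table)
        for j, lev in enumerate(levels):
            rows.append({
                "variable": var, "level": lev,
                "n_hydrocortisone": int(table[0, j]),
                "pct_hydrocortisone": 100.0 * table[0, j] / arm_tot[0]
                if arm_tot[0] else np.nan,
                "n_dexamethasone": int(table[1, j]),
                "pct_dexamethasone": 100.0 * table[1, j] / arm_tot[1]
                if arm_tot[1] else np.nan,
                "n_overall": int(overall[j]),
                "pct_overall": 100.0 * overall[j] / overall.sum(),
            })
        tests.append({"variable": var, "test": test_name, "p_value": p,
                      "significant_5pct": p < 0.05,
                      "n_missing": int(len(cohort) - len(sub))})

    for var in CONTINUOUS_VARS:
        sub = cohort[[var, TREATMENT_COL]].dropna()
        x0 = sub.loc[sub[TREATMENT_COL] == 0, var].to_numpy(float)
        x1 = sub.loc[sub[TREATMENT_COL] == 1, var].to_numpy(float)
        p = rank_sum_p(x0, x1)
        both = sub[var].to_numpy(float)
        row = {"variable": var, "level": "median [IQR]"}
        for name, vals in (("hydrocortisone", x0), ("dexamethasone", x1),
                           ("overall", both)):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row[f"median_{name}"] = float(med)
            row[f"iqr_low_{name}"] = float(q1)
            row[f"iqr_high_{name}"] = float(q3)
        rows.append(row)
        tests.append({"variable": var, "test": "Wilcoxon rank-sum",
                      "p_value": p, "significant_5pct": p < 0.05,
                      "n_missing": int(len(cohort) - len(sub))})

    return DescriptiveTable(rows=pd.DataFrame(rows), tests=pd.DataFrame(tests))


# ---------------------------------------------------------------------------
# study configuration and grid

@dataclass
class StudyConfig:
    """One-config description of a full estimation study."""

    cohort_csv: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    missingness: Optional[MissingnessSpec] = None
    imputation: ImputationSpec = field(default_factory=lambda: ImputationSpec(m=5))
    methods: Sequence[str] = ("par", "sl-dsl", "sl-nnls")
    datasets: Sequence[str] = ("imputed", "complete-case")
    pooling: str = "rubin"  # or "single"
    primary: tuple = ("sl-dsl", "imputed")
    sl_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.simulation is None):
            raise PipelineError("give exactly one of cohort_csv or simulation")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise PipelineError(f"unknown methods: {sorted(bad)}")
        bad = set(self.datasets) - set(DATASETS)
        if bad:
            raise PipelineError(f"unknown datasets: {sorted(bad)}")
        if self.pooling not in ("rubin", "single"):
            raise PipelineError(f"pooling must be 'rubin' or 'single'")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "StudyConfig":
        kwargs = dict(mapping)
        if isinstance(kwargs.get("simulation"), Mapping):
            kwargs["simulation"] = SimulationConfig.from_mapping(kwargs["simulation"])
        if isinstance(kwargs.get("missingness"), Mapping):
            kwargs["missingness"] = MissingnessSpec(**kwargs["missingness"])
        if isinstance(kwargs.get("imputation"), Mapping):
            kwargs["imputation"] = ImputationSpec(**kwargs["imputation"])
        if "primary" in kwargs:
            kwargs["primary"] = tuple(kwargs["primary"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(kwargs) - known
        if bad:
            raise PipelineError(f"unknown study-config fields: {sorted(bad)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@dataclass
class CellResult:
    """One (method, dataset) cell of the estimation grid."""

    method: str
    dataset: str
    estimate: Optional[ATEEstimate] = None
    error: Optional[str] = None
    pooled_m: int = 1


@dataclass
class StudyReport:
    """Estimation grid plus descriptive tables and provenance."""

    cells: list
    descriptives: dict
    config: StudyConfig
    primary: tuple

    def cell(self, method: str, dataset: str) -> CellResult:
        for c in self.cells:
            if (c.method, c.dataset) == (method, dataset):
                return c
        raise KeyError((method, dataset))

    def to_grid_frame(self) -> pd.DataFrame:
        recs = []
        for c in self.cells:
            rec = {"method": c.method, "dataset": c.dataset,
                   "primary": (c.method, c.dataset) == tuple(self.primary),
                   "pooled_m": c.pooled_m}
            if c.estimate is not None:
                e = c.estimate
                rec.update(psi=e.psi, se=e.se, ci_low=e.ci_low,
                           ci_high=e.ci_high, n=e.n)
            else:
                rec.update(error=c.error)
            recs.append(rec)
        return pd.DataFrame(recs)


def method_learners(method: str, sl_folds: int = 10):
    """(outcome strategy, propensity strategy) for a named method."""
    if method == "par":
        return (SingleLearner(LearnerSpec("glm", "binomial")),
                SingleLearner(LearnerSpec("glm", "binomial")))
    if method == "tree":
        return (SingleLearner(LearnerSpec("tree_ensemble", "binomial")),
                SingleLearner(LearnerSpec("tree_ensemble", "binomial")))
    if method in ("sl-dsl", "sl-nnls"):
        meta = "discrete" if method == "sl-dsl" else "nnls"
        lib = default_library("binomial")
        return (StackedLearner(lib, V=sl_folds, meta=meta),
                StackedLearner(lib, V=sl_folds, meta=meta))
    raise PipelineError(f"unknown method {method!r}")


def naive_fill(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median/mode single fill of the analysis columns (transparent
    reconstruction of package-style pre-processing; no uncertainty)."""
    df = cohort.copy()
    for col in ANALYSIS_COLS:
        if col == TREATMENT_COL or not df[col].isna().any():
            continue
        if col in CONTINUOUS_VARS:
            df[col] = df[col].fillna(df[col].median())
        else:
            df[col] = df[col].fillna(df[col].mode().iloc[0])
    return df


def _build_datasets(cohort: pd.DataFrame, config: StudyConfig
                    ) -> dict[str, list[pd.DataFrame]]:
    out: dict[str, object] = {}
    has_missing = cohort[ANALYSIS_COLS].isna().any().any()
    for name in config.datasets:
        try:
            if name == "imputed":
                if has_missing:
                    spec = dataclasses.replace(config.imputation,
                                               seed=config.seed + 2)
                    out[name] = fit_chained_imputation(cohort, spec).imputations
                else:
                    out[name] = [cohort]
            elif name == "complete-case":
                out[name] = [complete_case_filter(cohort)]
            elif name == "naive-fill":
                out[name] = [naive_fill(cohort)]
        except Exception as exc:  # noqa: BLE001 - recorded per grid cell
            out[name] = exc
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full method x dataset grid; deterministic given the seed.

    Per-stage seeds are derived from the master seed by fixed offsets.  A
    failing cell is recorded with its error and the run continues.
    """
    config.validate()
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort, _ = generate_cohort(sim)
        if config.missingness is not None:
            from .simulate import inject_missingness
            cohort = inject_missingness(cohort, config.missingness,
                                        seed=config.seed + 1)
    else:
        cohort = read_cohort(config.cohort_csv)
        if config.missingness is not None:
            from .simulate import inject_missingness
            cohort = inject_missingness(cohort, config.missingness,
                                        seed=config.seed + 1)

    datasets = _build_datasets(cohort, config)
    descriptives = {name: descriptive_table(tables[0])
                    for name, tables in datasets.items()
                    if not isinstance(tables, Exception)}

    cells = []
    for mi, method in enumerate(config.methods):
        for di, dataset in enumerate(config.datasets):
            tables = datasets.get(dataset, [])
            cell_seed = config.seed + 100 + 17 * mi + 3 * di
            if isinstance(tables, Exception):
                cells.append(CellResult(method, dataset,
                                        error=f"dataset build failed: {tables}"))
                continue
            try:
                out_l, prop_l = method_learners(method, config.sl_folds)
                use = tables if (dataset == "imputed"
                                 and config.pooling == "rubin") else tables[:1]
                ests = [tmle_ate(t, out_l, prop_l, seed=cell_seed,
                                 method_label=method, dataset_label=dataset)
                        for t in use]
                if len(ests) == 1:
                    est = ests[0]
                else:
                    est = pool_rubin(ests).to_ate_estimate(
                        n=ests[0].n, method_label=method,
                        dataset_label=dataset)
                cells.append(CellResult(method, dataset, estimate=est,
                                        pooled_m=len(ests)))
            except Exception as exc:  # noqa: BLE001 - grid keeps running
                cells.append(CellResult(method, dataset, error=str(exc)))
    return StudyReport(cells=cells, descriptives=descriptives, config=config,
                       primary=tuple(config.primary))


# ---------------------------------------------------------------------------
# forest export

def ci_overlap_matrix(report: StudyReport) -> pd.DataFrame:
    """Boolean matrix: do the 95% intervals of two cells overlap?"""
    good = [c for c in report.cells if c.estimate is not None]
    labels = [f"{c.method}|{c.dataset}" for c in good]
    mat = np.zeros((len(good), len(good)), dtype=bool)
    for i, ci in enumerate(good):
        for j, cj in enumerate(good):
            mat[i, j] = (ci.estimate.ci_low <= cj.estimate.ci_high
                         and cj.estimate.ci_low <= ci.estimate.ci_high)
    return pd.DataFrame(mat, index=labels, columns=labels)


def export_forest(report: StudyReport, path=None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forest table (label, psi, ci bounds) plus the CI overlap matrix.

    When ``path`` is given, both are written to one TSV (the overlap
    matrix appended after a comment line).
    """
    good = [c for c in report.cells if c.estimate is not None]
    if not good:
        raise PipelineError("report holds no successful estimates")
    forest = pd.DataFrame([
        {"label": f"{c.method}|{c.dataset}", "psi": c.estimate.psi,
         "ci_low": c.estimate.ci_low, "ci_high": c.estimate.ci_high}
        for c in good])
    overlap = ci_overlap_matrix(report)
    if path is not None:
        with open(path, "w") as fh:
            forest.to_csv(fh, sep="\t", index=False)
            fh.write("# pairwise 95% CI overlap matrix\n")
            overlap.to_csv(fh, sep="\t")
    return forest, overlap


def write_report(report: StudyReport, out_dir) -> None:
    """Write table1 per dataset, the grid, the forest TSV and a run log."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, desc in report.descriptives.items():
        desc.rows.to_csv(out / f"table1_{name}.tsv", sep="\t", index=False)
        desc.tests.to_csv(out / f"table1_{name}_tests.tsv", sep="\t", index=False)
    report.to_grid_frame().to_csv(out / "table2_grid.tsv", sep="\t", index=False)
    export_forest(report, out / "forest.tsv")
    log = {"seed": report.config.seed, "targetmle_version": __version__,
           "numpy_version": np.__version__, "pandas_version": pd.__version__,
           "methods": list(report.config.methods),
           "datasets": list(report.config.datasets),
           "pooling": report.config.pooling,
           "primary": list(report.primary)}
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
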