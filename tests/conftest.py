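"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from targetmle import SimulationConfig, generate_cohort
from targetmle.cohort import ALL_COLS


@pytest.fixture(scope="session")
def small_cohort():
    """Complete synthetic cohort, n = 300, additive truth tau = 2."""
    cohort, truth = generate_cohort(SimulationConfig(n=300, seed=42))
    return cohort, truth


def _fill_binary(n: int, k: int) -> np.ndarray:
    """Column of n values with exactly k ones (order immaterial for counts)."""
    col = np.zeros(n, dtype=int)
    col[:k] = 1
    return col


@pytest.fixture(scope="session")
def printed_counts_cohort():
    """168-row cohort reproducing the published cross-tabulation counts.

    40 hydrocortisone / 128 dexamethasone rows; within each arm every
    categorical column carries the published per-arm level counts
    (ventilation invasive 5/25, female 22/72, hypertension 22/87,
    hyperlipidaemia 3/17, diabetes 26/70, HIV no/yes/unknown 32/6/2 and
    101/14/13, CKD 4/9, asthma 1/6).  Continuous values are synthetic
    placeholders: only counts and percentages are meaningful here.
    """
    arm_counts = {
        0: dict(n=40, ventilation=5, gender=22, hypertension=22,
                hyperlipidaemia=3, diabetes=26, ckd=4, asthma=1,
                hiv=(32, 6, 2)),
        1: dict(n=128, ventilation=25, gender=72, hypertension=87,
                hyperlipidaemia=17, diabetes=70, ckd=9, asthma=6,
                hiv=(101, 14, 13)),
    }
    frames = []
    rng = np.random.default_rng(7)
    for arm, c in arm_counts.items():
        n = c["n"]
        df = pd.DataFrame({
            "age": rng.uniform(40, 70, n).round(1),
            "gender": _fill_binary(n, c["gender"]),
            "ventilation": _fill_binary(n, c["ventilation"]),
            "hypertension": _fill_binary(n, c["hypertension"]),
            "hyperlipidaemia": _fill_binary(n, c["hyperlipidaemia"]),
            "diabetes": _fill_binary(n, c["diabetes"]),
            "ckd": _fill_binary(n, c["ckd"]),
            "asthma": _fill_binary(n, c["asthma"]),
            "hiv": np.repeat(["no", "yes", "unknown"], c["hiv"]),
            "nlr_d1": rng.uniform(5, 20, n),
            "nlr_d5": rng.uniform(8, 30, n),
            "treatment": arm,
        })
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df["lymph_d1"] = 1.0
    df["neut_d1"] = df["nlr_d1"]
    df["lymph_d5"] = 1.0
    df["neut_d5"] = df["nlr_d5"]
    return df[ALL_COLS]
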