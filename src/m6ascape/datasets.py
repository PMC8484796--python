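"""Packaged reference data.

Ships the 21-gene m6A regulator panel with writer/eraser/reader categories,
the published univariate Cox table for those regulators in pancreatic
cancer, and a synthetic clinical fixture whose marginal counts (sex, age,
vital status per cohort) match the published patient characteristics table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import ClinicalTable

__all__ = [
    "regulator_panel",
    "regulator_categories",
    "load_regulator_cox",
    "synthetic_clinical_fixture",
]


def _data_path(name: str):
    return resources.files("m6ascape.data").joinpath(name)


def regulator_panel() -> list[str]:
    """The 21 m6A regulator gene symbols (writers, erasers, readers)."""
    return list(_regulator_df()["gene"])


def regulator_categories() -> dict[str, str]:
    """Map gene symbol -> {writer, eraser, reader}."""
    df = _regulator_df()
    return dict(zip(df["gene"], df["category"]))


def _regulator_df() -> pd.DataFrame:
    with resources.as_file(_data_path("regulators.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_regulator_cox() -> pd.DataFrame:
    """Published univariate Cox results for the 21 regulators.

    Columns: gene, hazard_ratio, ci_low, ci_high, p_value.
    """
    with resources.as_file(_data_path("regulator_cox.tsv")) as p:
        return pd.read_csv(p, sep="\t")


# Marginal counts per cohort: (n_female, n_male, n_age_ge60, n_age_lt60,
# n_dead, n_alive).  Rows with unknown vital status are not generated.
_COHORT_MARGINS = {
    "TCGA": (80, 97, 123, 54, 92, 85),
    "PACA-AU": (88, 109, 115, 53, 152, 45),
    "PACA-CA": (43, 47, 67, 22, 58, 32),
}


def synthetic_clinical_fixture() -> ClinicalTable:
    """Synthetic per-patient clinical table matching published margins.

    Individual rows are fabricated (deterministically seeded survival
    times); only the cohort-level marginal counts of sex, age group and
    vital status are faithful to the published characteristics table.
    """
    rng = np.random.default_rng(20210917)
    frames = []
    for cohort, (nf, nm, ge60, lt60, dead, alive) in _COHORT_MARGINS.items():
        n = nf + nm
        sex = ["Female"] * nf + ["Male"] * nm
        age_group = (["ge60"] * ge60 + ["lt60"] * lt60
                     + ["unknown"] * (n - ge60 - lt60))
        event = [1] * dead + [0] * alive
        # deterministic interleave so margins stay uncorrelated by construction
        order = rng.permutation(n)
        os_time = np.round(rng.exponential(600.0, size=n) + 30.0, 1)
        frames.append(pd.DataFrame({
            "sample_id": [f"{cohort}-{i:04d}" for i in range(n)],
            "os_time": os_time,
            "os_event": np.asarray(event)[order],
            "sex": np.asarray(sex)[rng.permutation(n)],
            "age_group": np.asarray(age_group)[rng.permutation(n)],
            "cohort": cohort,
        }))
    return ClinicalTable(pd.concat(frames, ignore_index=True))
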