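"""Person-level cohort container, CSV reading/validation and prevalence summaries.

A cohort is a table with one row per respondent: an identifier, gender
(M/F), categorical demographics (age group, income quartile, education)
and one binary 0/1 column per disease in the catalog. Disease entries must
be complete and binary; demographic entries may be missing (they only enter
the regression stage, where listwise deletion is applied and logged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import DiseaseCatalog

GENDER_LEVELS = ("M", "F")
AGE_LEVELS = ("50-64", "65-74", "75plus")
INCOME_LEVELS = ("Q1", "Q2", "Q3", "Q4")
EDUCATION_LEVELS = ("Primary", "Secondary", "Tertiary")

DEMOGRAPHIC_LEVELS = {
    "gender": GENDER_LEVELS,
    "age_group": AGE_LEVELS,
    "income_q": INCOME_LEVELS,
    "education": EDUCATION_LEVELS,
}

DEMOGRAPHIC_COLUMNS = ("gender", "age_group", "income_q", "education")


class SchemaError(ValueError):
    """Input table does not have the required columns."""


class CohortValidationError(ValueError):
    """Input table has invalid cell values."""


@dataclass
class Cohort:
    """Validated person x disease table.

    ``df`` holds columns ``id``, the demographics and the catalog's disease
    codes (ordered as in the catalog). ``X`` exposes the binary disease
    matrix as an int8 array in catalog column order.
    """

    df: pd.DataFrame
    catalog: DiseaseCatalog
    missing_demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df, self.catalog)
        self.missing_demographics = {
            col: int(self.df[col].isna().sum()) for col in DEMOGRAPHIC_COLUMNS
        }

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.catalog.codes)].to_numpy(dtype=np.int8)

    @property
    def person_ids(self) -> pd.Series:
        return self.df["id"]

    def disease_counts(self) -> np.ndarray:
        return self.X.sum(axis=1)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.df.loc[mask].reset_index(drop=True), self.catalog)

    def stratum(self, column: str, level: str) -> "Cohort":
        return self.subset((self.df[column] == level).to_numpy())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _validate_frame(df: pd.DataFrame, catalog: DiseaseCatalog) -> pd.DataFrame:
    required = ["id", *DEMOGRAPHIC_COLUMNS, *catalog.codes]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df[required].copy().reset_index(drop=True)
    for col in catalog.codes:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            rows = df.index[bad].tolist()
            raise CohortValidationError(
                f"non-binary value in disease column {col!r} at row(s) {rows[:10]}"
            )
        df[col] = vals.astype(np.int8)
    df["id"] = df["id"].astype(str)
    for col, levels in DEMOGRAPHIC_LEVELS.items():
        ser = df[col].astype("object")
        ser = ser.where(ser.notna() & (ser != ""), other=pd.NA)
        bad = ser.notna() & ~ser.isin(levels)
        if bad.any():
            raise CohortValidationError(
                f"invalid {col} value(s) {sorted(set(ser[bad]))}; allowed: {levels}"
            )
        df[col] = pd.Categorical(ser, categories=levels)
    return df


def read_cohort(path, catalog: DiseaseCatalog | None = None) -> Cohort:
    """Read and validate a cohort CSV (comma-separated, UTF-8, header row).

    Raises :class:`SchemaError` naming the first missing column and
    :class:`CohortValidationError` citing offending rows for non-binary
    disease cells.
    """
    catalog = catalog or DiseaseCatalog.default()
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    return Cohort(df, catalog)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_csv(path)


def filter_multimorbid(cohort: Cohort, min_diseases: int = 2) -> Cohort:
    """Retain exactly the persons carrying ``min_diseases`` or more conditions.

    Row order is preserved; ``min_diseases=0`` is the identity.
    """
    if min_diseases < 0:
        raise ValueError("min_diseases must be >= 0")
    mask = cohort.disease_counts() >= min_diseases
    return cohort.subset(mask)


def summarize_prevalence(cohort: Cohort, stratify: str | None = None) -> pd.DataFrame:
    """Per-disease prevalence, optionally split by a categorical field.

    Returns a tidy table with columns ``disease, stratum, count, n,
    proportion, defined``. A declared stratum level with zero persons is
    reported with ``defined=False`` rather than a propagating NaN.
    """
    codes = list(cohort.catalog.codes)
    rows = []
    if stratify is None:
        groups = [("all", cohort.df)]
    else:
        if stratify not in DEMOGRAPHIC_LEVELS:
            raise ValueError(f"not a categorical cohort field: {stratify!r}")
        groups = [
            (level, cohort.df[cohort.df[stratify] == level])
            for level in DEMOGRAPHIC_LEVELS[stratify]
        ]
    for level, sub in groups:
        n = len(sub)
        for code in codes:
            count = int(sub[code].sum()) if n else 0
            rows.append(
                {
                    "disease": code,
                    "stratum": level,
                    "count": count,
                    "n": n,
                    "proportion": (count / n) if n else float("nan"),
                    "defined": n > 0,
                }
            )
    table = pd.DataFrame(rows)
    if (~table["defined"]).any():
        empty = sorted(set(table.loc[~table["defined"], "stratum"]))
        warnings.warn(f"empty stratum level(s) {empty}: proportions undefined")
    return table
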