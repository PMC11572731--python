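"""Patient-level cohort container and CSV round-trip.

A cohort is one row per patient: race group (BA/WA), demographics,
disease-modifying-therapy (DMT) category, zip-code income, FLAIR lesion
burden, paramagnetic-rim-lesion (PRL) burden, and the EDSS disability
outcome.  The mediator of the downstream analysis is ``prl_percentage``,
the share of a patient's FLAIR lesions that carry a paramagnetic rim.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CohortValidationError

#: Canonical column order of the cohort CSV.
COLUMNS = [
    "patient_id",
    "race",
    "age",
    "sex",
    "disease_duration",
    "dmt",
    "zip_income",
    "flair_count",
    "flair_volume",
    "prl_count",
    "prl_percentage",
    "non_prl_volume",
    "edss",
]

RACE_LEVELS = ("BA", "WA")
SEX_LEVELS = ("male", "female")
DMT_LEVELS = ("higher", "lower", "untreated")

_NUMERIC_COLUMNS = [
    "age",
    "disease_duration",
    "zip_income",
    "flair_count",
    "flair_volume",
    "prl_count",
    "prl_percentage",
    "non_prl_volume",
    "edss",
]


@dataclasses.dataclass
class PatientRecord:
    """One subject's covariates, lesion burden, mediator value and outcome."""

    patient_id: str
    race: str
    age: float
    sex: str
    disease_duration: float
    dmt: str
    zip_income: float
    flair_count: int
    flair_volume: float
    prl_count: int
    prl_percentage: float
    non_prl_volume: float
    edss: float


@dataclasses.dataclass
class CohortTable:
    """Ordered collection of patient records plus provenance metadata."""

    df: pd.DataFrame
    seed: int | None = None
    mode: str | None = None
    config_digest: str | None = None
    #: Latent structural quantities (mediator/outcome residuals, confounder),
    #: attached only when the generator is asked to keep them.
    latents: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[PatientRecord]:
        for row in self.df.itertuples(index=False):
            yield PatientRecord(*row)

    def group(self, race: str) -> pd.DataFrame:
        return self.df[self.df["race"] == race]

    @property
    def n_ba(self) -> int:
        return int((self.df["race"] == "BA").sum())

    @property
    def n_wa(self) -> int:
        return int((self.df["race"] == "WA").sum())


def _fail(row, column, message):
    where = f"row {row}, column '{column}'" if row is not None else f"column '{column}'"
    raise CohortValidationError(f"{where}: {message}")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort column contract and per-row invariants.

    Returns the validated frame (with columns in canonical order).  Raises
    :class:`CohortValidationError` naming the offending row and column.
    """
    for col in COLUMNS:
        if col not in df.columns:
            _fail(None, col, "missing required column")
    df = df[COLUMNS].copy()

    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any():
            _fail(int(df.index[df[col].isna()][0]), col, "missing value")
        if bad.any():
            _fail(int(df.index[bad][0]), col, f"non-numeric value {df[col][bad].iloc[0]!r}")
        df[col] = coerced

    for col, levels in (("race", RACE_LEVELS), ("sex", SEX_LEVELS), ("dmt", DMT_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            _fail(int(df.index[bad][0]), col,
                  f"value {df[col][bad].iloc[0]!r} not in {levels}")

    checks = [
        ("age", df["age"] < 0, "age must be >= 0"),
        ("disease_duration", df["disease_duration"] < 0, "disease duration must be >= 0"),
        ("zip_income", df["zip_income"] <= 0, "income must be > 0"),
        ("flair_count", df["flair_count"] < 1, "every patient must have >= 1 FLAIR lesion"),
        ("prl_count", df["prl_count"] < 0, "PRL count must be >= 0"),
        ("prl_count", df["prl_count"] > df["flair_count"],
         "invariant violated: prl_count <= flair_count"),
        ("non_prl_volume", df["non_prl_volume"] < 0, "volume must be >= 0"),
        ("non_prl_volume",
         df["non_prl_volume"] > df["flair_volume"] * (1 + 1e-9),
         "invariant violated: non_prl_volume <= flair_volume"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            _fail(int(df.index[bad][0]), col, msg)

    for col in ("flair_count", "prl_count"):
        frac = df[col] % 1
        if (frac != 0).any():
            _fail(int(df.index[frac != 0][0]), col, "count must be an integer")
        df[col] = df[col].astype(np.int64)
    return df


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write the cohort as a headered CSV, one row per patient.

    Floats are written at full precision so that write-followed-by-read is
    the identity on every field.
    """
    path = Path(path)
    cohort.df[COLUMNS].to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV surface as validation errors
        raise CohortValidationError(f"could not parse {path}: {exc}") from exc
    df = validate_cohort(df)
    df["patient_id"] = df["patient_id"].astype(str)
    return CohortTable(df=df)
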