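"""Participant-level cohort table: schema, validation and CSV I/O.

The cohort table is a plain :class:`pandas.DataFrame` with one row per
participant. Columns:

================  =======================================================
``participant``   string id, unique
``sex``           ``"boy"`` or ``"girl"``
``age``           years (>= 0)
``body_mass``     kg, optional (may be NaN)
``height``        cm, optional (may be NaN)
``tibia_length``  cm (> 0)
``fibula_length`` cm (> 0)
``V_<muscle>``    absolute volume in cm³ for each of the 10 muscle groups
``motion_artefact`` bool QC flag (image corrupted by movement)
``included``      bool; False rows are excluded from analysis
================  =======================================================

TSURAE (LG+MG+SOL) and TOTAL (all 10 groups) are always derived on the
fly, never stored, so they cannot drift out of sync with the per-muscle
columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .muscles import MUSCLES, SEXES, TSURAE_MUSCLES


def volume_col(muscle: str) -> str:
    return f"V_{muscle}"


VOLUME_COLUMNS: tuple[str, ...] = tuple(volume_col(m) for m in MUSCLES)

COLUMNS: tuple[str, ...] = (
    "participant",
    "sex",
    "age",
    "body_mass",
    "height",
    "tibia_length",
    "fibula_length",
    *VOLUME_COLUMNS,
    "motion_artefact",
    "included",
)


class CohortError(ValueError):
    """Malformed cohort table."""


def empty_cohort() -> pd.DataFrame:
    """An empty cohort table with the full schema."""
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _dtypes().items()})
    return df


def _dtypes() -> dict[str, str]:
    d: dict[str, str] = {"participant": "string", "sex": "string"}
    for c in ("age", "body_mass", "height", "tibia_length", "fibula_length", *VOLUME_COLUMNS):
        d[c] = "float64"
    d["motion_artefact"] = "bool"
    d["included"] = "bool"
    return d


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the (unmodified) table.

    Raises
    ------
    CohortError
        On missing columns, unknown sex codes, non-positive volumes or
        tibia lengths in included rows, or negative ages.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        return df
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise CohortError(f"unknown sex codes: {sorted(bad_sex)}")
    if (df["age"] < 0).any():
        raise CohortError("negative ages present")
    inc = df[df["included"].astype(bool)]
    if (inc["tibia_length"] <= 0).any():
        raise CohortError("non-positive tibia length in included rows")
    vols = inc[list(VOLUME_COLUMNS)].to_numpy(float)
    if not np.all(np.isfinite(vols)) or (vols <= 0).any():
        raise CohortError("missing or non-positive muscle volume in included rows")
    if df["participant"].duplicated().any():
        raise CohortError("duplicate participant ids")
    return df


def total_volume(df: pd.DataFrame) -> pd.Series:
    """TOTAL: sum of the 10 muscle-group volumes (cm³), derived per row."""
    return df[list(VOLUME_COLUMNS)].sum(axis=1).rename("TOTAL")


def tsurae_volume(df: pd.DataFrame) -> pd.Series:
    """TSURAE: triceps surae volume LG + MG + SOL (cm³), derived per row."""
    return df[[volume_col(m) for m in TSURAE_MUSCLES]].sum(axis=1).rename("TSURAE")


def log_volume_matrix(df: pd.DataFrame) -> np.ndarray:
    """n × 10 matrix of natural-log absolute volumes in canonical order."""
    vols = df[list(VOLUME_COLUMNS)].to_numpy(float)
    if (vols <= 0).any() or not np.all(np.isfinite(vols)):
        raise CohortError("log-volume matrix requires strictly positive volumes")
    return np.log(vols)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort table as CSV (documented header, no index)."""
    validate_cohort(df)
    df.to_csv(path, index=False, columns=list(COLUMNS))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path, dtype={"participant": "string", "sex": "string"})
    for c in ("motion_artefact", "included"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return validate_cohort(df)
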