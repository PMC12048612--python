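"""Cohort readers/writers and sample quality control.

The cohort exchange format is delimited text (TSV by default) with a
header row and mandatory columns ``id, group, sex, age, a1, a2``; any
further columns are carried along as phenotypes.  Group and sex labels
are accepted case-insensitively and written back in canonical form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alleles import MIN_REPEAT

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("id", "group", "sex", "age", "a1", "a2")
CANONICAL_GROUPS = {"mdd": "MDD", "anx": "ANX", "con": "CON"}
CANONICAL_SEX = {"f": "female", "female": "female", "m": "male", "male": "male"}


class SchemaError(ValueError):
    pass


@dataclass
class QcReport:
    """Record-level exclusions applied while loading a cohort."""

    n_input: int = 0
    n_no_dna: int = 0  # allele cells empty: no DNA sample
    n_genotyping_failed: int = 0  # allele cells non-numeric: failed genotyping
    n_invalid: int = 0  # other validation failures
    n_swapped: int = 0  # a1 > a2 auto-swapped
    rejected_lines: list[int] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return self.n_input - self.n_no_dna - self.n_genotyping_failed - self.n_invalid


def apply_qc(df: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Apply record-level exclusions to a raw cohort table.

    Rows with empty allele cells are counted as missing DNA; rows whose
    allele cells are present but not valid integers are counted as
    failed genotyping; rows failing other validation (bad age, unknown
    group/sex, allele below 7) are rejected with their line numbers.
    Rows with a1 > a2 are auto-swapped with a warning.
    """
    report = QcReport(n_input=len(df))
    df = df.copy()

    a1_raw = df["a1"].astype("string").str.strip()
    a2_raw = df["a2"].astype("string").str.strip()
    missing = a1_raw.isna() | a2_raw.isna() | (a1_raw == "") | (a2_raw == "")
    a1_num = pd.to_numeric(a1_raw, errors="coerce")
    a2_num = pd.to_numeric(a2_raw, errors="coerce")
    failed = ~missing & (a1_num.isna() | a2_num.isna())
    report.n_no_dna = int(missing.sum())
    report.n_genotyping_failed = int(failed.sum())

    keep = ~(missing | failed)
    df = df[keep]
    df["a1"] = a1_num[keep].astype(float)
    df["a2"] = a2_num[keep].astype(float)

    df["group"] = df["group"].astype(str).str.strip().str.lower().map(CANONICAL_GROUPS)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower().map(CANONICAL_SEX)
    age = pd.to_numeric(df["age"], errors="coerce")
    invalid = (
        df["group"].isna()
        | df["sex"].isna()
        | age.isna()
        | (age <= 0)
        | (df["a1"] < MIN_REPEAT)
        | (df["a1"] != df["a1"].round())
        | (df["a2"] != df["a2"].round())
    )
    report.n_invalid = int(invalid.sum())
    report.rejected_lines = [int(i) + 2 for i in df.index[invalid]]  # 1-based + header
    if report.n_invalid:
        logger.warning(
            "%d rows rejected at lines %s", report.n_invalid, report.rejected_lines
        )
    df = df[~invalid].copy()
    df["age"] = age[~invalid]

    swap = df["a1"] > df["a2"]
    report.n_swapped = int(swap.sum())
    if report.n_swapped:
        logger.warning("%d rows with a1 > a2 auto-swapped", report.n_swapped)
        a1, a2 = df.loc[swap, "a1"].copy(), df.loc[swap, "a2"].copy()
        df.loc[swap, "a1"], df.loc[swap, "a2"] = a2.to_numpy(), a1.to_numpy()
    df["a1"] = df["a1"].astype(int)
    df["a2"] = df["a2"].astype(int)
    return df.reset_index(drop=True), report


def read_cohort(
    path, sep: Optional[str] = None, with_report: bool = False
):
    """Read and validate a cohort table (TSV/CSV, header row).

    Returns the validated DataFrame (or ``(df, QcReport)`` when
    ``with_report``).  Raises :class:`SchemaError` when a mandatory
    column is missing.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"cohort file {path} lacks mandatory columns {missing}; "
            f"expected {list(MANDATORY_COLUMNS)}"
        )
    df, report = apply_qc(raw)
    for col in df.columns:
        if col not in MANDATORY_COLUMNS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass  # categorical phenotype column (e.g. coil type)
    if with_report:
        return df, report
    return df


def write_cohort(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a cohort table in the canonical column order."""
    path = Path(path)
    ordered = [c for c in MANDATORY_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in MANDATORY_COLUMNS
    ]
    df[ordered].to_csv(path, sep=sep, index=False)


def read_fragment_table(path, sep: str = "\t") -> pd.DataFrame:
    """Fragment table: sample_id, fragment_size[, replicate_size]."""
    df = pd.read_csv(path, sep=sep)
    if not {"sample_id", "fragment_size"} <= set(df.columns):
        raise SchemaError("fragment table needs columns sample_id, fragment_size")
    return df


def read_standards(path, sep: str = "\t"):
    """Size-standard table: fragment_size, repeat_count."""
    from .alleles import FragmentStandard

    df = pd.read_csv(path, sep=sep)
    if not {"fragment_size", "repeat_count"} <= set(df.columns):
        raise SchemaError("standards file needs columns fragment_size, repeat_count")
    return FragmentStandard(
        tuple(
            (float(s), int(r))
            for s, r in zip(df["fragment_size"], df["repeat_count"])
        )
    )
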