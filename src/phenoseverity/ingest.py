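"""Reading and validation of the minimal CDM-style event tables.

The pipeline consumes five comma-delimited, UTF-8 text files modelled on a
small subset of the OMOP common data model:

* ``condition_occurrence.csv`` — ``patient_id, phenotype_code, event_date``
* ``drug_exposure.csv``        — ``patient_id, drug_code, event_date``
* ``procedure_occurrence.csv`` — ``patient_id, procedure_code, code_system,
  event_date`` where ``code_system`` is ``HCPCS`` or ``ICD9PROC``
* ``fee_schedule.csv``         — ``procedure_code, rate_per_minute,
  typical_minutes`` (HCPCS only)
* ``reference_standard.csv``   — ``phenotype_code, label`` with label in
  ``{mild, severe}``

Phenotype codes are treated as opaque strings (SNOMED-CT concept ids in real
data).  Rows that fail validation are rejected, logged with their file row
number, and counted — never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODE_SYSTEMS = ("HCPCS", "ICD9PROC")
VALID_LABELS = ("mild", "severe")

#: required columns per table kind
SCHEMAS: dict[str, tuple[str, ...]] = {
    "conditions": ("patient_id", "phenotype_code", "event_date"),
    "drugs": ("patient_id", "drug_code", "event_date"),
    "procedures": ("patient_id", "procedure_code", "code_system", "event_date"),
    "fee_schedule": ("procedure_code", "rate_per_minute", "typical_minutes"),
    "reference": ("phenotype_code", "label"),
}

#: canonical file name per table kind
FILENAMES: dict[str, str] = {
    "conditions": "condition_occurrence.csv",
    "drugs": "drug_exposure.csv",
    "procedures": "procedure_occurrence.csv",
    "fee_schedule": "fee_schedule.csv",
    "reference": "reference_standard.csv",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class Dialect:
    """Delimiter and date-format settings for the input files.

    Dates default to ISO 8601 (``YYYY-MM-DD``): unambiguous and sortable.
    """

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"


@dataclass
class Rejection:
    """One rejected input row: 1-based file row number (header = row 1)."""

    row: int
    reason: str


@dataclass
class EventTables:
    """The validated event streams plus fee schedule and reference standard.

    ``reference`` may be ``None`` when no reference standard is supplied;
    the classification stages are then skipped downstream.
    """

    conditions: pd.DataFrame
    drugs: pd.DataFrame
    procedures: pd.DataFrame
    fee_schedule: pd.DataFrame
    reference: pd.DataFrame | None = None
    rejections: dict[str, list[Rejection]] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(len(v) for v in self.rejections.values())

    def reference_labels(self) -> pd.Series:
        """Reference standard as a Series: phenotype_code -> {mild, severe}."""
        if self.reference is None:
            raise ValueError("no reference standard loaded")
        return self.reference.set_index("phenotype_code")["label"]


def _require_columns(df: pd.DataFrame, kind: str, path: object) -> None:
    for col in SCHEMAS[kind]:
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )


def read_table(
    path: str | Path, kind: str, dialect: Dialect = Dialect()
) -> tuple[pd.DataFrame, list[Rejection]]:
    """Read and validate one table; return (valid rows, rejections).

    Validation is row-level: unparseable dates, empty codes, unknown
    ``code_system`` values, negative or non-finite fee entries and
    duplicate/invalid reference labels are rejected individually.  A missing
    column is a hard :class:`SchemaError` naming the column.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    _require_columns(df, kind, path)
    df = df[list(SCHEMAS[kind])]

    rejections: list[Rejection] = []
    # header occupies file row 1; data row i (0-based) is file row i + 2
    rows = df.index.to_numpy() + 2
    bad = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask & ~bad]:
            rejections.append(Rejection(int(rows[idx]), reason))
        bad.loc[mask] = True

    if "event_date" in df.columns:
        parsed = pd.to_datetime(
            df["event_date"], format=dialect.date_format, errors="coerce"
        )
        _flag(parsed.isna(), "unparseable event_date")
        df = df.assign(event_date=parsed)

    for col in ("phenotype_code", "drug_code", "procedure_code", "patient_id"):
        if col in df.columns:
            _flag(df[col].isna() | (df[col].str.strip() == ""), f"empty {col}")

    if kind == "procedures":
        _flag(
            ~df["code_system"].isin(VALID_CODE_SYSTEMS),
            f"code_system not in {VALID_CODE_SYSTEMS}",
        )
    if kind == "fee_schedule":
        for col in ("rate_per_minute", "typical_minutes"):
            vals = pd.to_numeric(df[col], errors="coerce")
            finite = pd.Series(np.isfinite(vals.to_numpy(dtype=float)), index=df.index)
            _flag(vals.isna() | ~finite | (vals < 0), f"invalid {col}")
            df = df.assign(**{col: vals})
    if kind == "reference":
        _flag(~df["label"].isin(VALID_LABELS), f"label not in {VALID_LABELS}")
        _flag(df["phenotype_code"].duplicated(keep="first"), "duplicate phenotype_code")

    kept = df[~bad].reset_index(drop=True)
    for rej in rejections:
        logger.warning("%s (%s): rejected row %d: %s", path, kind, rej.row, rej.reason)
    if rejections:
        logger.warning(
            "%s (%s): %d of %d rows rejected", path, kind, len(rejections), len(df)
        )
    return kept, rejections


def load_event_tables(
    paths: Mapping[str, str | Path], dialect: Dialect = Dialect()
) -> EventTables:
    """Load all event tables from a mapping of table kind to file path.

    ``paths`` must contain ``conditions``, ``drugs``, ``procedures`` and
    ``fee_schedule``; ``reference`` is optional.
    """
    required = ("conditions", "drugs", "procedures", "fee_schedule")
    for kind in required:
        if kind not in paths:
            raise ValueError(f"missing path for table {kind!r}")
    loaded: dict[str, pd.DataFrame] = {}
    rejections: dict[str, list[Rejection]] = {}
    for kind in (*required, "reference"):
        if kind not in paths:
            continue
        loaded[kind], rejections[kind] = read_table(paths[kind], kind, dialect)
    return EventTables(
        conditions=loaded["conditions"],
        drugs=loaded["drugs"],
        procedures=loaded["procedures"],
        fee_schedule=loaded["fee_schedule"],
        reference=loaded.get("reference"),
        rejections=rejections,
    )


def load_directory(directory: str | Path, dialect: Dialect = Dialect()) -> EventTables:
    """Load event tables from a directory using the canonical file names."""
    directory = Path(directory)
    paths = {
        kind: directory / name
        for kind, name in FILENAMES.items()
        if (directory / name).exists() or kind != "reference"
    }
    return load_event_tables(paths, dialect)


def write_event_tables(tables: EventTables, directory: str | Path) -> None:
    """Write the tables back out under the canonical file names (ISO dates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, name in FILENAMES.items():
        df = getattr(tables, "reference" if kind == "reference" else kind)
        if df is None:
            continue
        out = df.copy()
        if "event_date" in out.columns:
            out["event_date"] = out["event_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(directory / name, index=False)


def compute_prevalence(
    conditions: pd.DataFrame, denominator: int | None = None
) -> pd.Series:
    """Per-phenotype prevalence: distinct carriers / total distinct patients.

    A patient counts once per phenotype no matter how many events they have.
    The denominator defaults to the number of distinct patients in the
    condition table; pass ``denominator`` to use an externally supplied
    patient count instead.
    """
    if conditions.empty:
        raise ValueError("condition table is empty; prevalence undefined")
    n_total = denominator if denominator is not None else conditions["patient_id"].nunique()
    if n_total < 1:
        raise ValueError("prevalence denominator must be >= 1")
    carriers = conditions.groupby("phenotype_code")["patient_id"].nunique()
    return (carriers / n_total).rename("prevalence")


def filter_by_prevalence(prevalence: pd.Series, threshold: float) -> set[str]:
    """Codes with prevalence >= threshold (inclusive, 'at least')."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return set(prevalence.index[prevalence >= threshold])
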