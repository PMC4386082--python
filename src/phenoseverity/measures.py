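"""The five phenotype-level severity measures.

Each measure is a patient-level quantity averaged over every patient who
carries the phenotype (a *carrier* is any patient with at least one condition
event for the code):

* ``treatment_time``   — whole days between a carrier's first and last event
  of the code (a single event spans 0 days).
* ``n_comorbidities``  — distinct other condition codes on the carrier's
  whole record.
* ``n_medications``    — distinct drug codes on the carrier's whole record.
* ``n_procedures``     — procedure *events* on the carrier's record, both
  HCPCS and ICD-9 procedure codes; repeat procedures count each time.
* ``cost``             — sum over the carrier's HCPCS procedure events of
  ``rate_per_minute × typical_minutes``.  ICD-9 procedure events carry no
  fee information and contribute nothing; HCPCS codes missing from the fee
  schedule contribute 0 and are logged (real fee schedules are incomplete).

Counts are taken over the whole patient record with no time window, and no
visit-level linkage of events to the index condition is attempted.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .ingest import EventTables, compute_prevalence

logger = logging.getLogger(__name__)

#: the five measure columns of a severity profile, in canonical order
MEASURES = ("treatment_time", "n_comorbidities", "n_medications", "n_procedures", "cost")

_AGGS = ("mean", "median", "max")


def _carriers(conditions: pd.DataFrame, phenotype_code: str) -> pd.Index:
    mask = conditions["phenotype_code"] == phenotype_code
    if not mask.any():
        raise KeyError(f"phenotype code {phenotype_code!r} has no condition events")
    return pd.Index(conditions.loc[mask, "patient_id"].unique())


def _aggregate(values: pd.Series, agg: str) -> float:
    if agg not in _AGGS:
        raise ValueError(f"aggregation must be one of {_AGGS}")
    return float(getattr(values, agg)())


def treatment_time(
    conditions: pd.DataFrame, phenotype_code: str, agg: str = "mean"
) -> float:
    """Per-carrier first-to-last event span in days, aggregated over carriers.

    The aggregation defaults to the mean, matching how the other measures
    average patient-level quantities; ``median`` and ``max`` are available.
    """
    _carriers(conditions, phenotype_code)  # raises on unknown code
    events = conditions[conditions["phenotype_code"] == phenotype_code]
    span = events.groupby("patient_id")["event_date"].agg(lambda s: (s.max() - s.min()).days)
    return _aggregate(span.astype(float), agg)


def comorbidity_count(conditions: pd.DataFrame, phenotype_code: str) -> float:
    """Mean number of distinct other condition codes among carriers."""
    carriers = _carriers(conditions, phenotype_code)
    sub = conditions[conditions["patient_id"].isin(carriers)]
    distinct = sub.groupby("patient_id")["phenotype_code"].nunique()
    return float((distinct - 1).mean())  # minus the index code itself


def medication_count(
    conditions: pd.DataFrame, drugs: pd.DataFrame, phenotype_code: str
) -> float:
    """Mean number of distinct drug codes over carriers' whole records."""
    carriers = _carriers(conditions, phenotype_code)
    per_patient = drugs.groupby("patient_id")["drug_code"].nunique()
    return float(per_patient.reindex(carriers).fillna(0).mean())


def procedure_count(
    conditions: pd.DataFrame, procedures: pd.DataFrame, phenotype_code: str
) -> float:
    """Mean number of procedure events (all code systems) among carriers."""
    carriers = _carriers(conditions, phenotype_code)
    per_patient = procedures.groupby("patient_id").size()
    return float(per_patient.reindex(carriers).fillna(0).mean())


def _cost_per_patient(
    procedures: pd.DataFrame, fee_schedule: pd.DataFrame
) -> pd.Series:
    """Total billable amount per patient, HCPCS events only."""
    hcpcs = procedures[procedures["code_system"] == "HCPCS"]
    merged = hcpcs.merge(fee_schedule, on="procedure_code", how="left")
    missing = merged["rate_per_minute"].isna()
    if missing.any():
        n_codes = merged.loc[missing, "procedure_code"].nunique()
        logger.warning(
            "%d HCPCS events (%d distinct codes) missing from the fee schedule; "
            "they contribute 0 cost",
            int(missing.sum()),
            n_codes,
        )
    amount = (merged["rate_per_minute"] * merged["typical_minutes"]).fillna(0.0)
    return amount.groupby(merged["patient_id"]).sum()


def phenotype_cost(
    conditions: pd.DataFrame,
    procedures: pd.DataFrame,
    fee_schedule: pd.DataFrame,
    phenotype_code: str,
) -> float:
    """Mean billable procedure cost among carriers (HCPCS events only)."""
    carriers = _carriers(conditions, phenotype_code)
    per_patient = _cost_per_patient(procedures, fee_schedule)
    return float(per_patient.reindex(carriers).fillna(0).mean())


def build_profiles(
    tables: EventTables,
    codes: Iterable[str] | None = None,
    agg: str = "mean",
    denominator: int | None = None,
) -> pd.DataFrame:
    """Severity profiles for the retained phenotype codes.

    Returns one row per code with columns ``n_patients``, ``prevalence`` and
    the five measures of :data:`MEASURES`, sorted by code.  ``codes`` defaults
    to every code in the condition table.  All measures are computed with a
    single set of grouped passes, so large cohorts stay fast; results are
    identical to calling the per-measure functions code by code.
    """
    if agg not in _AGGS:
        raise ValueError(f"aggregation must be one of {_AGGS}")
    conds = tables.conditions
    if conds.empty:
        raise ValueError("condition table is empty")
    codes = sorted(set(conds["phenotype_code"].unique()) if codes is None else set(codes))
    if not codes:
        return pd.DataFrame(
            columns=["phenotype_code", "n_patients", "prevalence", *MEASURES]
        )
    missing = set(codes) - set(conds["phenotype_code"].unique())
    if missing:
        raise KeyError(f"codes with no condition events: {sorted(missing)[:5]}...")

    prevalence = compute_prevalence(conds, denominator=denominator)

    # carrier pairs and per-(patient, code) spans in days
    grouped = conds.groupby(["patient_id", "phenotype_code"])["event_date"]
    span = (grouped.max() - grouped.min()).dt.days.astype(float).rename("span")
    pairs = span.reset_index()

    # whole-record per-patient quantities
    n_codes = conds.groupby("patient_id")["phenotype_code"].nunique()
    n_drugs = tables.drugs.groupby("patient_id")["drug_code"].nunique()
    n_procs = tables.procedures.groupby("patient_id").size()
    cost = _cost_per_patient(tables.procedures, tables.fee_schedule)

    pid = pairs["patient_id"]
    pairs = pairs.assign(
        n_comorbidities=n_codes.reindex(pid).to_numpy(dtype=float) - 1.0,
        n_medications=n_drugs.reindex(pid).fillna(0).to_numpy(dtype=float),
        n_procedures=n_procs.reindex(pid).fillna(0).to_numpy(dtype=float),
        cost=cost.reindex(pid).fillna(0.0).to_numpy(dtype=float),
    )
    pairs = pairs[pairs["phenotype_code"].isin(codes)]

    by_code = pairs.groupby("phenotype_code")
    profiles = pd.DataFrame(
        {
            "n_patients": by_code.size(),
            "prevalence": prevalence.reindex(codes),
            "treatment_time": by_code["span"].agg(agg),
            "n_comorbidities": by_code["n_comorbidities"].mean(),
            "n_medications": by_code["n_medications"].mean(),
            "n_procedures": by_code["n_procedures"].mean(),
            "cost": by_code["cost"].mean(),
        }
    ).loc[codes]
    profiles.index.name = "phenotype_code"
    out = profiles.reset_index()
    bad = out[list(MEASURES)].to_numpy()
    if not np.all(np.isfinite(bad)) or (bad < 0).any():
        raise AssertionError("severity measures must be finite and non-negative")
    return out
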