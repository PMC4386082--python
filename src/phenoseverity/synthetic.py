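"""Synthetic EHR cohort generator with phenotype-level severity structure.

The generator emulates the statistical structure the severity pipeline
assumes, without any claim to clinical realism: each phenotype carries a
latent mild/severe class, and severe phenotypes are elevated on all five
measures through multiplicative effect sizes.  Two deliberate nuisance
features of real EHR data are reproduced:

* **chronic-mild confounders** — a fraction of mild phenotypes (think acne)
  receive severe-scale treatment times while staying mild on every other
  measure, so treatment time alone cannot separate the classes;
* **imperfect cost/procedure coupling** — procedure events are mostly HCPCS
  codes with fee-schedule entries, but a random subset of HCPCS codes is
  fee-less and a fraction of events use ICD-9 procedure codes (which carry
  no fee), so cost correlates with procedure count only loosely.

Patients may carry more than one phenotype, and carrier assignment is
severity-assortative (see :func:`generate_cohort`): a patient's phenotypes
share a severity class, emulating the comorbidity clustering of
hospital-derived records, so whole-record measures retain the configured
class contrast.
Per-carrier counts are negative-binomial (overdispersed) and treatment
spans log-normal (heavy-tailed); phenotype-level log-normal heterogeneity
keeps phenotypes of the same class from being clones.  Severe phenotypes
get a prevalence boost by default, echoing the enrichment of sicker
individuals in hospital-derived data.

Everything is driven by one seed: a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import EventTables, write_event_tables

logger = logging.getLogger(__name__)

EPOCH = np.datetime64("2008-01-01")

#: measures that take a multiplicative severe-class effect size
EFFECT_KEYS = ("treatment_time", "comorbidities", "medications", "procedures", "cost")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a mid-sized hospital extract: 2000 patients, 500
    phenotypes of which 30% are severe, severe effect sizes of 3 on every
    measure, 10% of mild phenotypes chronic, and a reference standard
    covering 25% of phenotypes at the classic 372:144 mild:severe ratio.
    """

    n_patients: int = 2000
    n_phenotypes: int = 500
    severe_fraction: float = 0.3
    effect_sizes: dict = field(
        default_factory=lambda: {k: 3.0 for k in EFFECT_KEYS}
    )
    chronic_mild_fraction: float = 0.1
    reference_fraction: float = 0.25
    reference_ratio: tuple[int, int] = (372, 144)  # mild : severe
    severe_prevalence_boost: float = 1.5
    seed: int = 0

    # cohort-shape parameters (per-carrier baselines for a mild phenotype)
    mean_carriers: float = 6.0
    base_comorbidities: float = 3.0
    base_medications: float = 4.0
    base_procedures: float = 4.0
    nb_dispersion: float = 2.0
    span_median_days: float = 60.0
    span_sigma: float = 0.8
    phenotype_sigma: float = 0.3
    n_comorbidity_codes: int = 400
    n_drug_codes: int = 300
    n_hcpcs_codes: int = 60
    n_feeless_hcpcs: int = 10
    icd9_fraction: float = 0.2
    assortative: bool = True

    def __post_init__(self) -> None:
        for name in ("severe_fraction", "chronic_mild_fraction", "reference_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients < 1 or self.n_phenotypes < 1:
            raise ValueError("n_patients and n_phenotypes must be >= 1")
        if any(v < 1 for v in self.effect_sizes.values()):
            raise ValueError("effect sizes must be >= 1")


@dataclass
class SyntheticCohort:
    """Generated tables plus ground truth."""

    tables: EventTables
    truth: pd.DataFrame  # phenotype_code, label, chronic
    config: GeneratorConfig


def _neg_binomial(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    """Overdispersed counts with the given mean and dispersion r."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCohort:
    """Draw a full cohort: event tables, fee schedule, reference, truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    eff = {k: float(cfg.effect_sizes.get(k, 1.0)) for k in EFFECT_KEYS}

    codes = np.array([f"SCT{100000 + i}" for i in range(cfg.n_phenotypes)])
    severe = rng.random(cfg.n_phenotypes) < cfg.severe_fraction
    chronic = ~severe & (rng.random(cfg.n_phenotypes) < cfg.chronic_mild_fraction)

    # per-phenotype heterogeneity, one multiplier per measure
    mult = rng.lognormal(0.0, cfg.phenotype_sigma, size=(cfg.n_phenotypes, 5))

    drug_pool = np.array([f"RX{j:04d}" for j in range(cfg.n_drug_codes)])
    comorb_pool = np.array([f"CMB{j:04d}" for j in range(cfg.n_comorbidity_codes)])
    hcpcs_pool = np.array([f"H{j:04d}" for j in range(cfg.n_hcpcs_codes)])
    icd9_pool = np.array([f"I9P{j:03d}" for j in range(20)])
    rates = rng.lognormal(np.log(1.5), 0.6, cfg.n_hcpcs_codes)
    minutes = rng.integers(10, 90, cfg.n_hcpcs_codes).astype(float)
    feeless = rng.choice(cfg.n_hcpcs_codes, cfg.n_feeless_hcpcs, replace=False)
    has_fee = np.ones(cfg.n_hcpcs_codes, dtype=bool)
    has_fee[feeless] = False
    # severe carriers lean toward pricier codes (cost effect beyond volume)
    rate_rank = np.argsort(np.argsort(rates)) / max(cfg.n_hcpcs_codes - 1, 1)

    cond_rows: list[tuple] = []
    drug_rows: list[tuple] = []
    proc_rows: list[tuple] = []

    mean_carriers = cfg.mean_carriers * np.where(
        severe, cfg.severe_prevalence_boost, 1.0
    )
    n_carriers = 2 + rng.poisson(mean_carriers)
    n_carriers = np.minimum(n_carriers, cfg.n_patients)

    # Severity-assortative patient pools: severe phenotypes recruit carriers
    # from a "sicker" patient pool and mild phenotypes from the rest,
    # emulating the comorbidity clustering of hospital-derived records (sick
    # patients accumulate severe diagnoses).  Pool sizes are proportional to
    # each class's expected carrier demand so per-patient phenotype load is
    # matched across classes; whole-record measures then realise the
    # configured effect sizes instead of mixing signal across classes.
    demand = mean_carriers + 2.0
    sev_share = demand[severe].sum() / demand.sum() if severe.any() else 0.0
    perm = rng.permutation(cfg.n_patients)
    n_sick = int(round(sev_share * cfg.n_patients))
    if severe.any() and not severe.all():
        n_sick = min(max(n_sick, 1), cfg.n_patients - 1)
    sick_pool, robust_pool = perm[:n_sick], perm[n_sick:]
    if not cfg.assortative or not severe.any() or severe.all():
        sick_pool = robust_pool = perm

    for i in range(cfg.n_phenotypes):
        code = codes[i]
        e_tt = eff["treatment_time"] if (severe[i] or chronic[i]) else 1.0
        e_com = eff["comorbidities"] if severe[i] else 1.0
        e_med = eff["medications"] if severe[i] else 1.0
        e_proc = eff["procedures"] if severe[i] else 1.0
        cost_tilt = np.log(eff["cost"]) if severe[i] else 0.0

        pool = sick_pool if severe[i] else robust_pool
        carriers = rng.choice(pool, min(n_carriers[i], len(pool)), replace=False)
        m = len(carriers)
        first = rng.integers(0, 1500, m)
        spans = np.round(
            rng.lognormal(np.log(cfg.span_median_days * mult[i, 0] * e_tt), cfg.span_sigma, m)
        ).astype(int)
        n_com = _neg_binomial(rng, cfg.base_comorbidities * mult[i, 1] * e_com, cfg.nb_dispersion, m)
        n_med = _neg_binomial(rng, cfg.base_medications * mult[i, 2] * e_med, cfg.nb_dispersion, m)
        n_proc = _neg_binomial(rng, cfg.base_procedures * mult[i, 3] * e_proc, cfg.nb_dispersion, m)

        hcpcs_w = np.exp(cost_tilt * rate_rank)
        hcpcs_w /= hcpcs_w.sum()

        for j in range(m):
            pid = f"P{carriers[j]:06d}"
            d0 = EPOCH + first[j]
            cond_rows.append((pid, code, d0))
            if spans[j] >= 1:
                cond_rows.append((pid, code, d0 + spans[j]))
            if n_com[j] > 0:
                for cmb in rng.choice(comorb_pool, min(n_com[j], len(comorb_pool)), replace=False):
                    cond_rows.append((pid, cmb, d0 + int(rng.integers(0, spans[j] + 1))))
            if n_med[j] > 0:
                for dc in rng.choice(drug_pool, min(n_med[j], len(drug_pool)), replace=False):
                    drug_rows.append((pid, dc, d0 + int(rng.integers(0, spans[j] + 1))))
            for _ in range(n_proc[j]):
                when = d0 + int(rng.integers(0, spans[j] + 1))
                if rng.random() < cfg.icd9_fraction:
                    proc_rows.append((pid, str(rng.choice(icd9_pool)), "ICD9PROC", when))
                else:
                    proc_rows.append(
                        (pid, str(rng.choice(hcpcs_pool, p=hcpcs_w)), "HCPCS", when)
                    )

    conditions = pd.DataFrame(cond_rows, columns=["patient_id", "phenotype_code", "event_date"])
    drugs = pd.DataFrame(drug_rows, columns=["patient_id", "drug_code", "event_date"])
    procedures = pd.DataFrame(
        proc_rows, columns=["patient_id", "procedure_code", "code_system", "event_date"]
    )
    for df in (conditions, drugs, procedures):
        df["event_date"] = pd.to_datetime(df["event_date"])

    fee_schedule = pd.DataFrame(
        {
            "procedure_code": hcpcs_pool[has_fee],
            "rate_per_minute": np.round(rates[has_fee], 4),
            "typical_minutes": minutes[has_fee],
        }
    )

    truth = pd.DataFrame(
        {
            "phenotype_code": codes,
            "label": np.where(severe, "severe", "mild"),
            "chronic": chronic,
        }
    )

    reference = _draw_reference(rng, truth, cfg)

    tables = EventTables(
        conditions=conditions,
        drugs=drugs,
        procedures=procedures,
        fee_schedule=fee_schedule,
        reference=reference,
    )
    return SyntheticCohort(tables=tables, truth=truth, config=cfg)


def _draw_reference(
    rng: np.random.Generator, truth: pd.DataFrame, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Reference standard: a labelled subset at the configured class ratio."""
    n_ref = int(round(cfg.reference_fraction * cfg.n_phenotypes))
    mild_w, severe_w = cfg.reference_ratio
    n_sev = int(round(n_ref * severe_w / (mild_w + severe_w)))
    n_mild = n_ref - n_sev
    mild_codes = truth.loc[truth["label"] == "mild", "phenotype_code"].to_numpy()
    sev_codes = truth.loc[truth["label"] == "severe", "phenotype_code"].to_numpy()
    n_mild = min(n_mild, len(mild_codes))
    n_sev = min(n_sev, len(sev_codes))
    picked_mild = rng.choice(mild_codes, n_mild, replace=False)
    picked_sev = rng.choice(sev_codes, n_sev, replace=False)
    ref = pd.DataFrame(
        {
            "phenotype_code": np.concatenate([picked_mild, picked_sev]),
            "label": ["mild"] * n_mild + ["severe"] * n_sev,
        }
    ).sort_values("phenotype_code", kind="mergesort", ignore_index=True)
    return ref


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the five CSVs plus ``truth_labels.csv``."""
    directory = Path(directory)
    write_event_tables(cohort.tables, directory)
    cohort.truth.to_csv(directory / "truth_labels.csv", index=False)


def worked_fixture() -> SyntheticCohort:
    """A tiny hand-checkable cohort: 4 patients, 3 phenotypes.

    Every measure is computable by hand; the expected severity profiles are
    committed as a golden file in the test suite.  Includes a single-event
    phenotype (treatment time 0) and a phenotype whose only procedure is an
    ICD-9 code (cost 0).
    """
    d = pd.Timestamp
    conditions = pd.DataFrame(
        [
            ("p1", "SEVERE1", d("2010-01-01")),
            ("p1", "SEVERE1", d("2010-01-11")),
            ("p1", "MILD1", d("2010-02-01")),
            ("p2", "SEVERE1", d("2010-03-05")),
            ("p3", "MILD1", d("2010-01-01")),
            ("p3", "MILD1", d("2010-01-03")),
            ("p4", "CHRONIC1", d("2010-05-01")),
        ],
        columns=["patient_id", "phenotype_code", "event_date"],
    )
    drugs = pd.DataFrame(
        [
            ("p1", "RX01", d("2010-01-02")),
            ("p1", "RX02", d("2010-01-05")),
            ("p3", "RX01", d("2010-01-02")),
        ],
        columns=["patient_id", "drug_code", "event_date"],
    )
    procedures = pd.DataFrame(
        [
            ("p1", "H0001", "HCPCS", d("2010-01-02")),
            ("p1", "H0001", "HCPCS", d("2010-01-09")),
            ("p1", "I9P01", "ICD9PROC", d("2010-01-03")),
            ("p3", "H0002", "HCPCS", d("2010-01-02")),
            ("p4", "I9P01", "ICD9PROC", d("2010-05-01")),
        ],
        columns=["patient_id", "procedure_code", "code_system", "event_date"],
    )
    fee_schedule = pd.DataFrame(
        {
            "procedure_code": ["H0001", "H0002"],
            "rate_per_minute": [2.0, 1.0],
            "typical_minutes": [30.0, 15.0],
        }
    )
    reference = pd.DataFrame(
        {
            "phenotype_code": ["CHRONIC1", "MILD1", "SEVERE1"],
            "label": ["mild", "mild", "severe"],
        }
    )
    truth = reference.assign(chronic=[False, False, False])
    tables = EventTables(
        conditions=conditions,
        drugs=drugs,
        procedures=procedures,
        fee_schedule=fee_schedule,
        reference=reference,
    )
    cfg = replace(GeneratorConfig(), n_patients=4, n_phenotypes=3)
    return SyntheticCohort(tables=tables, truth=truth, config=cfg)
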