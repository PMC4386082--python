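"""End-to-end pipeline: ingest → measures → E-PSI → forest → calls → report.

Every run writes a fixed set of text outputs to the output directory:

* ``severity_profiles.csv`` — per-phenotype measures and prevalence
* ``epsi_scores.csv``       — per-phenotype proportions and E-PSI
* ``embedding.csv``         — 2-D classical-scaling coordinates
* ``importance.csv``        — per-feature mean decrease in Gini
* ``classification.csv``    — mild/severe call and neighbour support
* ``evaluation.json``       — confusion metrics, error-curve endpoints,
  per-measure class contrasts
* ``run_report.json``       — seed, config echo, versions, stage summaries

When no reference standard is supplied the classification and evaluation
stages are skipped; measures and E-PSI are still produced.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import epsi as epsi_mod
from . import evaluation as ev
from . import forest as forest_mod
from . import ingest, measures

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run settings; defaults follow the method's stated operating point
    (prevalence threshold 0.0001, 1000 trees) with k=15 neighbour votes."""

    input_dir: str
    output_dir: str
    prevalence_threshold: float = 0.0001
    n_trees: int = 1000
    k_neighbors: int = 15
    seed: int = 0
    treatment_time_agg: str = "mean"
    epsi_divide_by_n: bool = True
    denominator: int | None = None
    min_carriers: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.select_dtypes(include=[float]).columns:
        out[col] = out[col].map(lambda v: format(v, ".10g"))
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    _float_fmt(df).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "versions": {
            "phenoseverity": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return deco

    @stage("ingest")
    def tables():
        t = ingest.load_directory(config.input_dir)
        report["rejected_rows"] = {k: len(v) for k, v in t.rejections.items()}
        return t

    @stage("prevalence_filter")
    def retained():
        prevalence = ingest.compute_prevalence(
            tables.conditions, denominator=config.denominator
        )
        keep = ingest.filter_by_prevalence(prevalence, config.prevalence_threshold)
        report["n_phenotypes_total"] = int(prevalence.size)
        report["n_phenotypes_retained"] = len(keep)
        return keep

    @stage("profiles")
    def profiles():
        p = measures.build_profiles(
            tables,
            codes=retained,
            agg=config.treatment_time_agg,
            denominator=config.denominator,
        )
        p = p[p["n_patients"] >= config.min_carriers]
        _write_csv(p, out_dir / "severity_profiles.csv")
        return p

    @stage("epsi")
    def scores():
        s = epsi_mod.compute_epsi(profiles, divide_by_n=config.epsi_divide_by_n)
        _write_csv(s, out_dir / "epsi_scores.csv")
        return s

    @stage("forest")
    def model():
        X = forest_mod.feature_matrix(profiles, scores)
        m = forest_mod.fit_unsupervised_forest(
            X, n_trees=config.n_trees, seed=config.seed
        )
        imp = m.importance.rename_axis("feature").reset_index()
        _write_csv(imp, out_dir / "importance.csv")
        report["importance"] = {
            k: float(v) for k, v in m.importance.items()
        }
        return m

    @stage("scaling")
    def embedding():
        coords = forest_mod.scale_proximity(model, n_dims=2)
        emb = pd.DataFrame(
            {"phenotype_code": model.codes, "dim1": coords[:, 0], "dim2": coords[:, 1]}
        )
        _write_csv(emb, out_dir / "embedding.csv")
        return coords

    if tables.reference is None:
        logger.info("no reference standard supplied; skipping classification")
        report["classification"] = None
        _write_report(report, out_dir)
        return report

    reference = tables.reference_labels()

    @stage("classify")
    def calls():
        c = forest_mod.classify_phenotypes(model, reference, k=config.k_neighbors)
        _write_csv(c, out_dir / "classification.csv")
        return c

    @stage("evaluate")
    def evaluation():
        anchors = [c for c in reference.index if c in set(model.codes)]
        called = calls.set_index("phenotype_code").loc[anchors, "label"]
        counts = ev.confusion_counts(reference.loc[anchors], called)
        metrics = ev.sensitivity_specificity(counts)
        curves = ev.error_curves(model, reference, k=config.k_neighbors)
        X = forest_mod.feature_matrix(profiles, scores)
        contrast = ev.measure_contrast_report(X, reference)
        space = forest_mod.severe_space_report(calls, model.embedding)
        payload = {
            "confusion": {
                "severe_positive": asdict(counts),
                "mild_positive": asdict(counts.swapped()),
            },
            "metrics": metrics,
            "final_error_rates": {
                "oob": float(curves["oob"].iloc[-1]),
                "severe": float(curves["severe"].iloc[-1]),
                "mild": float(curves["mild"].iloc[-1]),
            },
            "measure_contrast": contrast.to_dict(orient="records"),
            "severe_space": space,
        }
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    report["classification"] = {
        "n_called_severe": int((calls["label"] == "severe").sum()),
        "n_called_mild": int((calls["label"] == "mild").sum()),
    }
    report["evaluation"] = {
        "metrics": evaluation["metrics"],
        "final_error_rates": evaluation["final_error_rates"],
    }
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
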