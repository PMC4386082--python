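"""Evaluation statistics: confusion metrics, rater agreement, rank tests.

Sensitivity/specificity are reported for both positive-class orientations
(severe-positive by default) because published operating points do not
always state which class was treated as positive.  Agreement uses Cohen's
kappa for a pair of raters and Fleiss' kappa for many raters; class
contrasts between mild and severe phenotypes use the two-sided Wilcoxon
rank-sum test, with quartiles rather than means since severity measures are
far from normal.  No multiple-testing correction is applied across the six
per-measure contrasts; the per-measure p-values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ProximityModel, _weighted_knn_vote
from .measures import MEASURES


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 counts with severe as the positive class unless stated otherwise."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive class flipped."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


def confusion_counts(
    truth: Sequence[str], predicted: Sequence[str], positive: str = "severe"
) -> ConfusionCounts:
    """Tabulate aligned truth/prediction label sequences."""
    t = np.asarray(truth) == positive
    p = np.asarray(predicted) == positive
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def sensitivity_specificity(counts: ConfusionCounts) -> dict:
    """Sensitivity and specificity in percent, for both orientations.

    A zero denominator leaves the corresponding value NaN and sets an
    ``undefined`` flag instead of raising.
    """

    def _pair(c: ConfusionCounts) -> tuple[float, float]:
        sens = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
        spec = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")
        return sens, spec

    sens, spec = _pair(counts)
    sens_m, spec_m = _pair(counts.swapped())
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_mild_positive": sens_m,
        "specificity_mild_positive": spec_m,
        "undefined": any(np.isnan(v) for v in (sens, spec)),
    }


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Chance-corrected agreement between two aligned label sequences.

    κ = (p_o − p_e) / (1 − p_e) with expected agreement p_e from the product
    of the two raters' marginals.  When both raters are constant and
    identical, p_e = 1 and κ is defined as 1 (perfect agreement).
    """
    a = pd.Series(list(rater_a))
    b = pd.Series(list(rater_b))
    if len(a) != len(b):
        raise ValueError("rater sequences must have equal length")
    if len(a) == 0:
        raise ValueError("rater sequences are empty")
    n = len(a)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    cats = sorted(set(a) | set(b))
    pa = a.value_counts().reindex(cats).fillna(0) / n
    pb = b.value_counts().reindex(cats).fillna(0) / n
    p_e = float((pa * pb).sum())
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(counts: np.ndarray | pd.DataFrame) -> float:
    """Fleiss' kappa from an item × category rater-count matrix.

    Every item must be rated by the same number of raters.  When expected
    agreement is 1 (all ratings in one category) κ is defined as 1.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValueError("counts must be a 2-D item × category matrix")
    totals = table.sum(axis=1)
    if totals.min() < 2 or not np.all(totals == totals[0]):
        raise ValueError("every item needs the same rater count (>= 2)")
    n_raters = totals[0]
    p_item = (np.sum(table * (table - 1), axis=1)) / (n_raters * (n_raters - 1))
    p_bar = float(p_item.mean())
    p_cat = table.sum(axis=0) / table.sum()
    p_e = float(np.sum(p_cat**2))
    if p_e >= 1.0:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def ratings_to_fleiss_counts(ratings: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format ratings (item, rater, label) to Fleiss counts."""
    return ratings.pivot_table(
        index="item", columns="label", values="rater", aggfunc="count", fill_value=0
    )


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test: returns (U statistic, p).

    ``mode='auto'`` enumerates the exact null when both samples have at most
    10 observations and the pooled data are tie-free, and otherwise uses the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == len(pooled)
        mode = "exact" if (len(x) <= 10 and len(y) <= 10 and tie_free) else "approx"
    if mode not in ("exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def error_curves(
    model: ProximityModel, reference: pd.Series, k: int = 15
) -> pd.DataFrame:
    """Discrimination error versus number of trees.

    Three series of length ``n_trees``: the forest's out-of-bag
    real-vs-synthetic error (``oob``) plus leave-one-out severe-class and
    mild-class error rates of the proximity-weighted k-NN read-out, rebuilt
    from the stored terminal-node memberships at every cumulative tree count.
    """
    code_pos = {c: i for i, c in enumerate(model.codes)}
    anchors = [c for c in reference.index if c in code_pos]
    if len(anchors) <= k:
        raise ValueError("not enough reference phenotypes for the k-NN read-out")
    idx = np.array([code_pos[c] for c in anchors])
    sev = (reference.loc[anchors] == "severe").to_numpy()
    L = model.leaves[idx]  # m × n_trees
    m = len(anchors)
    co = (L[:, None, :] == L[None, :, :]).astype(np.int32)
    cum = np.cumsum(co, axis=2)

    sev_err = np.empty(model.n_trees)
    mild_err = np.empty(model.n_trees)
    eye = np.eye(m, dtype=bool)
    for t in range(model.n_trees):
        prox = cum[:, :, t] / float(t + 1)
        prox = np.where(eye, -np.inf, prox)
        called_severe, _ = _weighted_knn_vote(prox, sev, k)
        sev_err[t] = float((~called_severe[sev]).mean())
        mild_err[t] = float(called_severe[~sev].mean())

    out = model.oob_error_curve[["n_trees", "oob"]].copy()
    out["severe"] = sev_err
    out["mild"] = mild_err
    return out


def measure_contrast_report(
    features: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Quartiles by severity class and rank-sum p for each of the 6 measures.

    ``features`` is indexed by phenotype code with the five measures and
    ``epsi`` as columns; ``labels`` maps a subset of those codes to
    mild/severe.  Returns one row per measure.
    """
    common = [c for c in labels.index if c in features.index]
    if not common:
        raise ValueError("no overlap between labels and feature rows")
    sub = features.loc[common]
    lab = labels.loc[common]
    rows = []
    for measure in (*MEASURES, "epsi"):
        if measure not in sub.columns:
            continue
        sev_vals = sub.loc[lab == "severe", measure].to_numpy()
        mild_vals = sub.loc[lab == "mild", measure].to_numpy()
        _, p = wilcoxon_rank_sum(sev_vals, mild_vals, mode="approx")
        q = lambda v, f: float(np.quantile(v, f)) if len(v) else float("nan")
        rows.append(
            {
                "measure": measure,
                "severe_q1": q(sev_vals, 0.25),
                "severe_median": q(sev_vals, 0.5),
                "severe_q3": q(sev_vals, 0.75),
                "mild_q1": q(mild_vals, 0.25),
                "mild_median": q(mild_vals, 0.5),
                "mild_q3": q(mild_vals, 0.75),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
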