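"""Unsupervised random-forest proximity model over the severity features.

The feature matrix has one row per phenotype and six columns: the five
severity measures plus E-PSI.  Following the unsupervised-forest
construction, a synthetic contrast sample is drawn from the product of the
observed marginals (each column resampled independently with replacement)
and an ensemble of classification trees is trained to discriminate observed
rows from synthetic rows.  Structure in the joint distribution of the
features — e.g. mild and severe phenotypes elevated together on several
measures — makes observed rows separable from the contrast sample, and rows
that co-occur in terminal nodes are similar under the metric the forest
learned.

The proximity of two observed rows is the fraction of all trees in which
they share a terminal node; it is symmetric, has unit diagonal, and lies in
[0, 1].  The 1 − proximity dissimilarity is embedded in the plane with
classical (Torgerson) scaling, and phenotypes are labelled mild or severe by
a proximity-weighted k-nearest-neighbour vote over reference-standard
anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .measures import MEASURES

logger = logging.getLogger(__name__)

#: fixed column order of the feature matrix
FEATURES = (*MEASURES, "epsi")


def feature_matrix(profiles: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join profiles and E-PSI scores into the six-feature matrix.

    Rows are indexed by phenotype code, columns follow :data:`FEATURES`.
    """
    merged = profiles.merge(scores[["phenotype_code", "epsi"]], on="phenotype_code")
    X = merged.set_index("phenotype_code")[list(FEATURES)]
    if X.isna().any().any() or not np.isfinite(X.to_numpy()).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    return X


@dataclass
class ProximityModel:
    """Trained forest artifacts.

    ``proximity`` is the n×n all-trees co-occurrence fraction; ``leaves``
    stores per-tree terminal-node ids of the observed rows (needed to rebuild
    proximities at intermediate tree counts); ``oob_error_curve`` tracks the
    real-vs-synthetic discrimination error versus number of trees.
    """

    codes: list[str]
    proximity: np.ndarray
    importance: pd.Series
    oob_error_curve: pd.DataFrame
    leaves: np.ndarray
    n_trees: int
    seed: int
    embedding: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        P = self.proximity
        if not np.allclose(P, P.T):
            raise AssertionError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(P), 1.0):
            raise AssertionError("proximity diagonal must be 1")
        if P.min() < 0 or P.max() > 1 + 1e-12:
            raise AssertionError("proximity entries must lie in [0, 1]")


def make_contrast_sample(
    features: pd.DataFrame, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Synthetic contrast class: independent column-wise resampling.

    Each synthetic column is a resample-with-replacement of the observed
    column, so marginals are preserved exactly while all dependence between
    columns is broken (the product of empirical marginals).
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows to build a contrast sample")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n = len(features)
    data = {
        col: features[col].to_numpy()[rng.integers(0, n, n)] for col in features.columns
    }
    return pd.DataFrame(data, index=[f"synthetic_{i}" for i in range(n)])


def fit_unsupervised_forest(
    features: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: str | int = "sqrt",
) -> ProximityModel:
    """Fit the real-vs-synthetic forest and compute proximities.

    Each tree is grown on a bootstrap sample of the stacked (observed +
    contrast) data with a random feature subset per split; tree induction is
    delegated to scikit-learn's CART trees while bootstrap draws, the
    contrast sample and all bookkeeping are controlled by one seed, so a
    fixed seed gives identical proximities, importances and error curves.

    Importance is the per-feature mean decrease in Gini impurity, averaged
    over trees on the count scale of the training sample.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(features) < 2:
        raise ValueError("need at least 2 phenotypes")
    rng = np.random.default_rng(seed)
    contrast = make_contrast_sample(features, rng)
    n = len(features)
    Z = np.vstack([features.to_numpy(dtype=float), contrast.to_numpy(dtype=float)])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    n_total = 2 * n

    leaves = np.empty((n, n_trees), dtype=np.int32)
    prox_counts = np.zeros((n, n), dtype=np.int32)
    importance = np.zeros(len(FEATURES))
    # signed OOB votes: +1 when the tree predicts "synthetic", 0 when in-bag
    votes = np.zeros((n_total, n_trees), dtype=np.int8)

    for t in range(n_trees):
        boot = rng.integers(0, n_total, n_total)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Z[boot], y[boot])
        leaf_all = tree.apply(Z)
        leaf = leaf_all[:n]
        leaves[:, t] = leaf
        prox_counts += leaf[:, None] == leaf[None, :]
        importance += tree.tree_.compute_feature_importances(normalize=False)
        oob = np.ones(n_total, dtype=bool)
        oob[np.unique(boot)] = False
        pred = tree.predict(Z[oob])
        votes[oob, t] = np.where(pred == 1, 1, -1)

    proximity = prox_counts / float(n_trees)
    np.fill_diagonal(proximity, 1.0)

    # cumulative-majority OOB error curves; ties count as errors
    cum = np.cumsum(votes.astype(np.int32), axis=1)
    ever_oob = np.cumsum(votes != 0, axis=1) > 0
    pred_syn = cum > 0
    wrong = (pred_syn != (y[:, None] == 1)) | (cum == 0)
    wrong &= ever_oob

    def _err(mask: np.ndarray) -> np.ndarray:
        seen = ever_oob[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(seen > 0, wrong[mask].sum(axis=0) / seen, np.nan)

    curve = pd.DataFrame(
        {
            "n_trees": np.arange(1, n_trees + 1),
            "oob": _err(np.ones(n_total, dtype=bool)),
            "real": _err(y == 0),
            "synthetic": _err(y == 1),
        }
    )

    return ProximityModel(
        codes=list(features.index),
        proximity=proximity,
        importance=pd.Series(
            importance / n_trees * n_total, index=list(FEATURES), name="mean_decrease_gini"
        ),
        oob_error_curve=curve,
        leaves=leaves,
        n_trees=n_trees,
        seed=seed,
    )


def scale_proximity(model: ProximityModel, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of the 1 − proximity dissimilarity.

    Double-centres −½D², takes the top ``n_dims`` eigenvectors scaled by the
    square roots of their eigenvalues (clipped at zero: 1 − proximity need
    not be Euclidean, and any negative-eigenvalue mass is logged).  Each
    dimension's sign is fixed so its largest-magnitude coordinate is
    positive.  Dimensions beyond the rank of the configuration come back as
    zero columns, with a log message.
    """
    D = 1.0 - model.proximity
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = float(-eigval[eigval < 0].sum())
    if neg_mass > 1e-9:
        logger.info(
            "1-proximity is not exactly Euclidean: negative eigenvalue mass %.4g "
            "(clipped at zero)",
            neg_mass,
        )
    lam = np.clip(eigval[:n_dims], 0.0, None)
    if np.count_nonzero(lam > 1e-12) < n_dims:
        logger.info(
            "requested %d dimensions but configuration has rank %d; "
            "extra columns are zero",
            n_dims,
            int(np.count_nonzero(lam > 1e-12)),
        )
    coords = eigvec[:, :n_dims] * np.sqrt(lam)
    for d in range(coords.shape[1]):
        col = coords[:, d]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, d] = -col
    model.embedding = coords
    return coords


def _weighted_knn_vote(
    prox_to_anchors: np.ndarray,
    anchor_is_severe: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximity-weighted k-NN severity vote for each row.

    ``prox_to_anchors`` is rows × anchors; entries set to -inf are excluded
    (e.g. a row's own anchor column).  Ties in the weighted vote go to
    *severe*, matching a preference for flagging severe phenotypes.  Returns
    (is_severe, support) where support is the winning share of the summed
    neighbour proximity (0.5 on a tie or when all k proximities are zero).
    """
    n_anchors = prox_to_anchors.shape[1]
    k = min(k, n_anchors)
    part = np.argpartition(-prox_to_anchors, kth=k - 1, axis=1)[:, :k]
    w = np.take_along_axis(prox_to_anchors, part, axis=1)
    w = np.clip(w, 0.0, None)  # excluded -inf entries carry no weight
    sev_w = (w * anchor_is_severe[part]).sum(axis=1)
    total = w.sum(axis=1)
    is_severe = sev_w * 2 >= total
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(total > 0, np.maximum(sev_w, total - sev_w) / total, 0.5)
    return is_severe, support


def classify_phenotypes(
    model: ProximityModel,
    reference: pd.Series,
    k: int = 15,
) -> pd.DataFrame:
    """Label every phenotype mild/severe from its reference-standard neighbours.

    For each phenotype the ``k`` highest-proximity reference phenotypes
    (itself excluded) cast a proximity-weighted vote; ties go to severe.
    Reference phenotypes are therefore scored leave-one-out automatically.
    Returns ``phenotype_code, label, neighbor_support``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = model.codes
    code_pos = {c: i for i, c in enumerate(codes)}
    anchors = [c for c in reference.index if c in code_pos]
    if len(anchors) < k:
        raise ValueError(
            f"need at least k={k} reference phenotypes in the model; found {len(anchors)}"
        )
    anchor_idx = np.array([code_pos[c] for c in anchors])
    anchor_sev = (reference.loc[anchors] == "severe").to_numpy()

    prox = model.proximity[:, anchor_idx].astype(float).copy()
    for col, row in enumerate(anchor_idx):
        prox[row, col] = -np.inf  # never one's own neighbour
    is_severe, support = _weighted_knn_vote(prox, anchor_sev, k)
    return pd.DataFrame(
        {
            "phenotype_code": codes,
            "label": np.where(is_severe, "severe", "mild"),
            "neighbor_support": support,
        }
    )


def severe_space_report(
    calls: pd.DataFrame, embedding: np.ndarray | None = None
) -> dict:
    """Counts of mild/severe calls and the embedding extent of each class."""
    counts = calls["label"].value_counts().to_dict()
    report: dict = {
        "n_phenotypes": int(len(calls)),
        "n_mild": int(counts.get("mild", 0)),
        "n_severe": int(counts.get("severe", 0)),
    }
    report["severe_fraction"] = (
        report["n_severe"] / report["n_phenotypes"] if len(calls) else float("nan")
    )
    if embedding is not None:
        for label in ("mild", "severe"):
            mask = (calls["label"] == label).to_numpy()
            if mask.any():
                sub = embedding[mask]
                report[f"{label}_bbox"] = {
                    "min": sub.min(axis=0).tolist(),
                    "max": sub.max(axis=0).tolist(),
                }
    return report
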