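import numpy as np
import pandas as pd
import pytest

from phenoseverity.forest import (
    FEATURES,
    ProximityModel,
    classify_phenotypes,
    fit_unsupervised_forest,
    make_contrast_sample,
    scale_proximity,
    severe_space_report,
)


def _features(n, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    if informative:
        cls = rng.random(n) < 0.5
        base = np.where(cls[:, None], 10.0, 1.0)
        data = base * rng.lognormal(0, 0.1, size=(n, len(FEATURES)))
    else:
        data = rng.lognormal(0, 0.5, size=(n, len(FEATURES)))
    return pd.DataFrame(data, columns=list(FEATURES), index=[f"c{i:03d}" for i in range(n)])


def _model_from_proximity(prox, codes):
    n = len(codes)
    return ProximityModel(
        codes=list(codes),
        proximity=prox,
        importance=pd.Series(0.0, index=list(FEATURES)),
        oob_error_curve=pd.DataFrame({"n_trees": [1], "oob": [0.0], "real": [0.0], "synthetic": [0.0]}),
        leaves=np.zeros((n, 1), dtype=np.int32),
        n_trees=1,
        seed=0,
    )


class TestContrastSample:
    def test_constant_column_is_preserved_exactly(self):
        X = _features(30, seed=1)
        X["cost"] = 7.0
        synth = make_contrast_sample(X, seed=0)
        assert (synth["cost"] == 7.0).all()

    def test_values_are_resampled_from_observed(self):
        X = _features(30, seed=2)
        synth = make_contrast_sample(X, seed=0)
        for col in X.columns:
            assert set(synth[col]).issubset(set(X[col]))

    def test_deterministic_under_seed(self):
        X = _features(30, seed=3)
        pd.testing.assert_frame_equal(
            make_contrast_sample(X, seed=5), make_contrast_sample(X, seed=5)
        )

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            make_contrast_sample(_features(1), seed=0)


class TestForestFit:
    def test_proximity_invariants(self, small_model):
        P = small_model.proximity
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert P.min() >= 0 and P.max() <= 1

    def test_invalid_tree_count(self):
        with pytest.raises(ValueError):
            fit_unsupervised_forest(_features(10), n_trees=0)

    def test_determinism_under_seed(self):
        X = _features(40, seed=4)
        m1 = fit_unsupervised_forest(X, n_trees=50, seed=9)
        m2 = fit_unsupervised_forest(X, n_trees=50, seed=9)
        assert np.array_equal(m1.proximity, m2.proximity)
        pd.testing.assert_series_equal(m1.importance, m2.importance)
        assert np.array_equal(m1.leaves, m2.leaves)

    def test_constant_feature_has_negligible_importance(self):
        X = _features(80, seed=5)
        X["cost"] = 3.0  # uninformative: constant across all rows
        model = fit_unsupervised_forest(X, n_trees=200, seed=1)
        imp = model.importance
        assert imp["cost"] <= 0.05 * imp.max()

    def test_duplicate_row_has_high_proximity_to_twin(self):
        X = _features(40, seed=6)
        X = pd.concat([X, X.iloc[[0]].rename(index={"c000": "twin"})])
        model = fit_unsupervised_forest(X, n_trees=200, seed=2)
        P = model.proximity
        off_diag = P[~np.eye(len(P), dtype=bool)]
        assert P[0, -1] >= np.median(off_diag)

    def test_oob_error_curve_shape_and_range(self, small_model):
        curve = small_model.oob_error_curve
        assert len(curve) == small_model.n_trees
        for col in ("oob", "real", "synthetic"):
            vals = curve[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()


class TestClassicalScaling:
    def test_identical_points_embed_at_origin(self):
        prox = np.ones((4, 4))
        model = _model_from_proximity(prox, list("abcd"))
        coords = scale_proximity(model)
        assert np.allclose(coords, 0.0)

    def test_equilateral_configuration_recovered(self):
        prox = np.full((3, 3), 0.4)
        np.fill_diagonal(prox, 1.0)
        model = _model_from_proximity(prox, list("abc"))
        c = scale_proximity(model)
        d01 = np.linalg.norm(c[0] - c[1])
        d02 = np.linalg.norm(c[0] - c[2])
        d12 = np.linalg.norm(c[1] - c[2])
        assert abs(d01 - d02) < 1e-8 and abs(d01 - d12) < 1e-8

    def test_euclidean_dissimilarity_recovered_exactly(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 0.3, size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        model = _model_from_proximity(1.0 - D, [f"p{i}" for i in range(12)])
        c = scale_proximity(model, n_dims=2)
        D_hat = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        assert np.abs(D_hat - D).max() < 1e-6

    def test_sign_convention_largest_coordinate_positive(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 0.3, size=(10, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        model = _model_from_proximity(1.0 - D, [f"p{i}" for i in range(10)])
        c = scale_proximity(model)
        for d in range(2):
            assert c[np.argmax(np.abs(c[:, d])), d] >= 0

    def test_rank_deficient_extra_dims_are_zero(self):
        prox = np.full((3, 3), 0.4)
        np.fill_diagonal(prox, 1.0)
        model = _model_from_proximity(prox, list("abc"))
        c = scale_proximity(model, n_dims=3)
        assert np.allclose(c[:, 2], 0.0)


class TestClassification:
    def test_unanimous_severe_neighbors(self):
        prox = np.full((4, 4), 0.5)
        np.fill_diagonal(prox, 1.0)
        model = _model_from_proximity(prox, list("abcd"))
        ref = pd.Series({"a": "severe", "b": "severe", "c": "severe"})
        calls = classify_phenotypes(model, ref, k=3).set_index("phenotype_code")
        assert calls.loc["d", "label"] == "severe"
        assert calls.loc["d", "neighbor_support"] == 1.0

    def test_exact_tie_goes_to_severe(self):
        prox = np.full((3, 3), 0.5)
        np.fill_diagonal(prox, 1.0)
        model = _model_from_proximity(prox, list("abc"))
        ref = pd.Series({"a": "severe", "b": "mild"})
        calls = classify_phenotypes(model, ref, k=2).set_index("phenotype_code")
        assert calls.loc["c", "label"] == "severe"
        assert calls.loc["c", "neighbor_support"] == pytest.approx(0.5)

    def test_well_separated_clusters_recover_anchor_labels(self):
        rng = np.random.default_rng(10)
        n = 60
        cls = np.arange(n) % 2 == 0
        # inter-cluster gap far beyond 5 within-cluster SDs
        centers = np.where(cls[:, None], 100.0, 1.0)
        X = pd.DataFrame(
            centers + rng.normal(0, 0.5, size=(n, len(FEATURES))),
            columns=list(FEATURES),
            index=[f"c{i:02d}" for i in range(n)],
        ).abs()
        model = fit_unsupervised_forest(X, n_trees=200, seed=3)
        anchors = {}
        for i in range(20):
            anchors[f"c{i:02d}"] = "severe" if i % 2 == 0 else "mild"
        calls = classify_phenotypes(model, pd.Series(anchors), k=5).set_index("phenotype_code")
        truth = pd.Series(np.where(cls, "severe", "mild"), index=X.index)
        assert (calls["label"] == truth).all()

    def test_k_validation(self, small_model):
        with pytest.raises(ValueError):
            classify_phenotypes(small_model, pd.Series({"c": "mild"}), k=0)
        with pytest.raises(ValueError):
            classify_phenotypes(small_model, pd.Series({"nope": "mild"}), k=1)


class TestSeparabilityRecovery:
    """Classification quality tracks the planted class separation."""

    @staticmethod
    def _balanced_accuracy(effect, chronic, seed=11):
        from dataclasses import replace

        from phenoseverity.epsi import compute_epsi
        from phenoseverity.evaluation import confusion_counts, sensitivity_specificity
        from phenoseverity.forest import feature_matrix
        from phenoseverity.measures import build_profiles
        from phenoseverity.synthetic import GeneratorConfig, generate_cohort

        cfg = replace(
            GeneratorConfig(n_patients=400, n_phenotypes=80, seed=seed),
            effect_sizes={"treatment_time": effect, "comorbidities": effect,
                          "medications": effect, "procedures": effect, "cost": effect},
            chronic_mild_fraction=chronic,
        )
        cohort = generate_cohort(cfg)
        profiles = build_profiles(cohort.tables, codes=cohort.truth["phenotype_code"])
        X = feature_matrix(profiles, compute_epsi(profiles))
        model = fit_unsupervised_forest(X, n_trees=200, seed=seed)
        ref = cohort.tables.reference_labels()
        calls = classify_phenotypes(model, ref, k=5).set_index("phenotype_code")
        m = sensitivity_specificity(confusion_counts(ref, calls.loc[ref.index, "label"]))
        return (m["sensitivity"] + m["specificity"]) / 200.0

    def test_monotone_separability_over_effect_levels(self):
        """No effect -> chance-level balanced accuracy; strong effects ->
        near-perfect leave-one-out recovery of the anchor labels."""
        null = self._balanced_accuracy(1.0, chronic=0.0)
        mid = self._balanced_accuracy(1.8, chronic=0.1)
        strong = self._balanced_accuracy(3.0, chronic=0.1)
        assert 0.35 <= null <= 0.65
        assert mid >= 0.85 and strong >= 0.85
        assert null < mid and null < strong


class TestSevereSpaceReport:
    def test_counts_partition_phenotypes(self):
        calls = pd.DataFrame(
            {"phenotype_code": list("abcd"), "label": ["mild", "severe", "mild", "mild"]}
        )
        rep = severe_space_report(calls)
        assert rep["n_mild"] + rep["n_severe"] == rep["n_phenotypes"] == 4

    def test_all_mild(self):
        calls = pd.DataFrame({"phenotype_code": ["a"], "label": ["mild"]})
        assert severe_space_report(calls)["n_severe"] == 0

    def test_bounding_boxes(self):
        calls = pd.DataFrame(
            {"phenotype_code": list("ab"), "label": ["mild", "severe"]}
        )
        emb = np.array([[0.0, 1.0], [2.0, -1.0]])
        rep = severe_space_report(calls, emb)
        assert rep["severe_bbox"]["min"] == [2.0, -1.0]
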