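import warnings

import numpy as np
import pandas as pd
import pytest

from cropxfer.errors import ContractError, DegenerateDataError
from cropxfer.feature_curves import FeatureCurve
from cropxfer.sample_screening import (
    cluster_points,
    curve_summary_features,
    screen_samples,
    silhouette_coefficient,
    zscore,
)

from .oracles import brute_force_silhouette


def constant_curve(feature, value):
    return FeatureCurve(feature=feature, model="cubic",
                        coefficients=np.array([value, 0.0, 0.0, 0.0]),
                        doy_domain=(140.0, 290.0))


def linear_curve(feature, lo, hi, n=100):
    # crafted so a 100-point resampling yields linspace(lo, hi, n)
    slope = (hi - lo) / (290.0 - 140.0)
    return FeatureCurve(feature=feature, model="cubic",
                        coefficients=np.array([lo - slope * 140.0, slope, 0.0, 0.0]),
                        doy_domain=(140.0, 290.0))


class TestCurveSummaryFeatures:
    def test_constant_curve_stats(self):
        curves = {f: constant_curve(f, 0.7) for f in ("nir", "ndvi", "ndwi")}
        vec = curve_summary_features(curves)
        np.testing.assert_allclose(vec[:7], [0.7, 0.0, 0.7, 0.7, 0.7, 0.7, 0.7], atol=1e-12)

    def test_linear_1_to_100(self):
        curves = {"nir": linear_curve("nir", 1.0, 100.0)}
        vec = curve_summary_features(curves, features=("nir",))
        mean, sd, lo, hi, p25, p50, p75 = vec
        assert mean == pytest.approx(50.5)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(100.0)
        assert p50 == pytest.approx(50.5)
        assert p25 == pytest.approx(np.percentile(np.linspace(1, 100, 100), 25))

    def test_vector_length_21(self):
        curves = {f: constant_curve(f, 0.2) for f in ("nir", "ndvi", "ndwi")}
        assert len(curve_summary_features(curves)) == 21

    def test_order_statistics_sorted(self):
        rng = np.random.default_rng(0)
        curves = {"nir": FeatureCurve("nir", "cubic", rng.normal(0, 1e-5, 4) + [0.3, 0, 0, 0],
                                      (140.0, 290.0))}
        m, sd, lo, hi, p25, p50, p75 = curve_summary_features(curves, features=("nir",))
        assert lo <= p25 <= p50 <= p75 <= hi and sd >= 0

    def test_missing_feature_raises(self):
        with pytest.raises(ContractError, match="ndwi"):
            curve_summary_features({"nir": constant_curve("nir", 0.1)},
                                   features=("nir", "ndwi"))


def blob_features(n1, n2, gap=10.0, seed=0, dim=3):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.5, (n1, dim)), rng.normal(gap, 0.5, (n2, dim))])
    return X


class TestClusterPoints:
    def test_two_blobs_recovered(self):
        X = blob_features(20, 15)
        labels = cluster_points(X, 2, seed=1)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cluster_points(np.ones((10, 3)), 2, seed=0)

    def test_determinism(self):
        X = blob_features(15, 15, gap=3.0, seed=2)
        np.testing.assert_array_equal(cluster_points(X, 3, seed=5),
                                      cluster_points(X, 3, seed=5))

    def test_k_bounds(self):
        X = blob_features(3, 2)
        with pytest.raises(ContractError):
            cluster_points(X, 5, seed=0)
        with pytest.raises(ContractError):
            cluster_points(X, 1, seed=0)


class TestSilhouetteCoefficient:
    def test_hand_computed_example(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = silhouette_coefficient(X, np.array([0, 0, 1, 1]))
        assert res.sc == pytest.approx(0.99, abs=1e-3)
        np.testing.assert_allclose(res.per_point_a, 0.1)

    def test_overlapping_clusters_near_zero(self):
        scs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (40, 3))
            labels = rng.integers(0, 2, 40)
            if len(set(labels.tolist())) < 2:
                continue
            scs.append(silhouette_coefficient(X, labels).sc)
        assert abs(np.mean(scs)) <= 0.1

    def test_range_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 25)
            X = rng.normal(0, 1, (n, 2))
            labels = rng.integers(0, 3, n)
            if len(set(labels.tolist())) < 2:
                continue
            res = silhouette_coefficient(X, labels)
            assert np.all(res.per_point_s >= -1) and np.all(res.per_point_s <= 1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(2, 5))
            X = rng.normal(0, 1, (n, 3))
            labels = rng.integers(0, k, n)
            if len(set(labels.tolist())) < 2:
                continue
            res = silhouette_coefficient(X, labels)
            s_oracle, sc_oracle = brute_force_silhouette(X, labels)
            np.testing.assert_allclose(res.per_point_s, s_oracle, atol=1e-10)
            assert res.sc == pytest.approx(sc_oracle, abs=1e-10)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        res = silhouette_coefficient(X, np.array([0, 0, 1]))
        assert res.per_point_s[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ContractError):
            silhouette_coefficient(np.zeros((4, 2)), np.zeros(4))


def potential_frame(X, crop="maize", sims=None, ids=None):
    n = len(X)
    df = pd.DataFrame({
        "id": ids or [f"p_s{i:04d}" for i in range(n)],
        "source_id": [f"s{i:04d}" for i in range(n)],
        "year": 2018, "row": np.arange(n), "col": np.arange(n),
        "offset_row": 0, "offset_col": 0,
        "class": crop, "provenance": "potential",
        "similarity": sims if sims is not None else np.full(n, 0.9),
    })
    for j in range(X.shape[1]):
        df[f"cf_{j:02d}"] = X[:, j]
    return df


class TestScreenSamples:
    def test_sixty_forty_blobs(self):
        X = blob_features(60, 40, gap=12.0, seed=3, dim=21)
        generated, report = screen_samples(potential_frame(X), k_max=8, seed=1)
        rep = report["per_crop"]["maize"]
        assert rep["k_star"] == 2
        assert len(generated) == 60
        assert set(generated["source_id"]) == {f"s{i:04d}" for i in range(60)}

    def test_homogeneous_blob_majority_bound(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 21))
        generated, report = screen_samples(potential_frame(X), k_max=8, seed=2)
        rep = report["per_crop"]["maize"]
        assert rep["k_star"] is not None
        assert len(generated) >= 50 / rep["k_star"]  # majority-cluster bound
        if rep["k_star"] == 2:
            assert len(generated) >= 25

    def test_retained_subset_and_classes_kept(self):
        X = blob_features(30, 20, gap=8.0, seed=6, dim=21)
        pot = potential_frame(X, crop="rice")
        generated, _ = screen_samples(pot, k_max=6, seed=0)
        assert set(generated["source_id"]) <= set(pot["source_id"])
        assert (generated["class"] == "rice").all()
        assert (generated["provenance"] == "generated").all()

    def test_small_crop_passthrough_warns(self):
        X = np.random.default_rng(0).normal(0, 1, (3, 21))
        with pytest.warns(UserWarning, match="screening skipped"):
            generated, report = screen_samples(potential_frame(X), seed=0)
        assert len(generated) == 3
        assert report["per_crop"]["maize"]["screened"] is False

    def test_empty_input(self):
        with pytest.warns(UserWarning, match="no potential samples"):
            generated, _ = screen_samples(potential_frame(np.zeros((0, 21))), seed=0)
        assert len(generated) == 0

    def test_degenerate_features_passthrough(self):
        X = np.ones((10, 21))
        with pytest.warns(UserWarning, match="degenerate"):
            generated, _ = screen_samples(potential_frame(X), seed=0)
        assert len(generated) == 10

    def test_retained_fraction_at_least_inverse_k(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (45, 21))
        _, report = screen_samples(potential_frame(X), k_max=10, seed=4)
        rep = report["per_crop"]["maize"]
        assert rep["retained_fraction"] >= 1.0 / rep["k_star"] - 1e-12

    def test_per_crop_grouping(self):
        Xa = blob_features(20, 10, gap=9.0, seed=1, dim=21)
        Xb = blob_features(12, 18, gap=9.0, seed=2, dim=21)
        pot = pd.concat([
            potential_frame(Xa, crop="maize", ids=[f"p_a{i}" for i in range(30)]),
            potential_frame(Xb, crop="rice", ids=[f"p_b{i}" for i in range(30)]),
        ], ignore_index=True)
        generated, report = screen_samples(pot, k_max=6, seed=3)
        assert set(report["per_crop"]) == {"maize", "rice"}
        assert (generated.groupby("class").size() <= 30).all()
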