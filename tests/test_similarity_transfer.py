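import warnings

import numpy as np
import pandas as pd
import pytest

from cropxfer.errors import ContractError, IncomparablePixelError
from cropxfer.feature_curves import FeatureCurve
from cropxfer.similarity_transfer import (
    _window_offsets,
    dtw_distance,
    pixel_similarity,
    select_potential_samples,
    similarity_from_distance,
)

from .conftest import make_scene_pair, purity
from .oracles import brute_force_dtw


def constant_curve(feature, value):
    return FeatureCurve(feature=feature, model="cubic",
                        coefficients=np.array([value, 0.0, 0.0, 0.0]),
                        doy_domain=(140.0, 290.0))


class TestDtwDistance:
    def test_identity(self):
        a = np.array([0.3, 0.5, 0.2, 0.9])
        assert dtw_distance(a, a) == 0.0

    def test_constant_offset(self):
        # derived by exhaustive path enumeration: diagonal path, cost 3x1
        assert dtw_distance([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == pytest.approx(3.0)
        assert brute_force_dtw([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == pytest.approx(3.0)

    def test_exact_warp_is_free(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == pytest.approx(0.0)
        assert brute_force_dtw([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = rng.random(rng.integers(1, 7))
            b = rng.random(rng.integers(1, 7))
            assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b = rng.random(8), rng.random(5)
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            assert dtw_distance(rng.random(6), rng.random(9)) >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            dtw_distance([], [1.0])


class TestSimilarityFromDistance:
    def test_zero_distance(self):
        assert similarity_from_distance(0.0, 100, 100) == 1.0

    def test_reference_value(self):
        assert similarity_from_distance(56.0, 100, 100) == pytest.approx(0.5712, abs=1e-4)

    def test_monotone_decreasing(self):
        s = [similarity_from_distance(d, 100, 100) for d in np.linspace(0, 500, 50)]
        assert all(x > y for x, y in zip(s, s[1:]))

    def test_uses_max_length(self):
        assert similarity_from_distance(10.0, 5, 100) == pytest.approx(np.exp(-0.1))

    def test_invalid_inputs(self):
        with pytest.raises(ContractError):
            similarity_from_distance(-1.0, 10, 10)
        with pytest.raises(ContractError):
            similarity_from_distance(1.0, 0, 10)


class TestPixelSimilarity:
    def test_identical_curve_sets(self):
        curves = {f: constant_curve(f, 0.4) for f in ("nir", "ndvi", "ndwi")}
        score = pixel_similarity(curves, dict(curves))
        assert score.similarity == pytest.approx(1.0)

    def test_aggregate_is_mean_of_per_feature(self):
        # constant curves: DTW distance = n * |delta|, so S = exp(-|delta|)
        deltas = {"nir": -np.log(0.6), "ndvi": -np.log(0.5), "ndwi": -np.log(0.4)}
        hist = {f: constant_curve(f, 0.0) for f in deltas}
        target = {f: constant_curve(f, d) for f, d in deltas.items()}
        score = pixel_similarity(hist, target)
        assert score.per_feature["nir"] == pytest.approx(0.6)
        assert score.per_feature["ndvi"] == pytest.approx(0.5)
        assert score.per_feature["ndwi"] == pytest.approx(0.4)
        assert score.similarity == pytest.approx(0.5)

    def test_partial_feature_overlap(self):
        hist = {f: constant_curve(f, 0.0) for f in ("nir", "ndvi", "ndwi")}
        target = {"nir": constant_curve("nir", 0.0), "ndvi": constant_curve("ndvi", 0.0)}
        score = pixel_similarity(hist, target)
        assert set(score.per_feature) == {"nir", "ndvi"}
        assert score.similarity == pytest.approx(1.0)

    def test_no_shared_feature(self):
        with pytest.raises(IncomparablePixelError):
            pixel_similarity({"nir": constant_curve("nir", 0.1)},
                             {"ndwi": constant_curve("ndwi", 0.1)})


class TestWindowOffsets:
    def test_center_first(self):
        offs = _window_offsets(5)
        assert offs[0] == (0, 0)
        assert len(offs) == 25
        dists = [max(abs(r), abs(c)) for r, c in offs]
        assert dists == sorted(dists)


class TestSelectPotentialSamples:
    def test_clean_scene_selects_center(self, clean_scene, feature_models):
        pot, skips = select_potential_samples(
            clean_scene["samples"], clean_scene["stacks"][2017],
            clean_scene["stacks"][2018], feature_models)
        assert len(skips) == 0
        centered = (pot["offset_row"] == 0) & (pot["offset_col"] == 0)
        assert centered.mean() >= 0.95

    def test_at_most_one_per_historical_sample(self, small_scene, feature_models):
        pot, skips = select_potential_samples(
            small_scene["samples"], small_scene["stacks"][2017],
            small_scene["stacks"][2018], feature_models)
        assert len(pot) + len(skips) == len(small_scene["samples"])
        assert pot["source_id"].is_unique
        assert np.all(pot["offset_row"].abs() <= 2) and np.all(pot["offset_col"].abs() <= 2)
        assert np.all((pot["similarity"] > 0) & (pot["similarity"] <= 1))

    def test_same_crop_similarity_dominates(self, feature_models):
        # aggregate S at a same-crop pixel beats a different-crop pixel
        _, stacks, truth = make_scene_pair(seed=23, noise_sd=0.02, grid=32, n_fields=16)
        from cropxfer.feature_curves import feature_cube, fit_pixel_curves

        hist_cube = feature_cube(stacks[2017], tuple(feature_models))
        tgt_cube = feature_cube(stacks[2018], tuple(feature_models))
        labels = truth.labels(2018)
        wins = trials = 0
        rng = np.random.default_rng(0)
        pixels = rng.permutation(32 * 32)
        curves_at = {}

        def curves(cube, stack, r, c):
            key = (id(cube), r, c)
            if key not in curves_at:
                curves_at[key] = fit_pixel_curves(cube, stack.dates, r, c, feature_models)
            return curves_at[key]

        for p in pixels[:40]:
            r, c = divmod(int(p), 32)
            hist = curves(hist_cube, stacks[2017], r, c)
            if hist is None:
                continue
            same = np.argwhere(labels == labels[r, c])
            diff = np.argwhere(labels != labels[r, c])
            if len(diff) == 0:
                continue
            rs, cs = same[rng.integers(len(same))]
            rd, cd = diff[rng.integers(len(diff))]
            cs_curves = curves(tgt_cube, stacks[2018], int(rs), int(cs))
            cd_curves = curves(tgt_cube, stacks[2018], int(rd), int(cd))
            if cs_curves is None or cd_curves is None:
                continue
            s_same = pixel_similarity(hist, cs_curves).similarity
            s_diff = pixel_similarity(hist, cd_curves).similarity
            trials += 1
            wins += s_same > s_diff
        assert trials >= 20
        assert wins / trials >= 0.9

    def test_singleton_neighborhood(self, clean_scene, feature_models):
        stacks = clean_scene["stacks"]
        target = stacks[2018]
        # invalidate everything except one neighbor of the first sample
        rec = clean_scene["samples"].iloc[[0]]
        r, c = int(rec["row"].iloc[0]), int(rec["col"].iloc[0])
        bands = target.bands.copy()
        valid = np.zeros_like(target.valid_mask)
        valid[:, r + 1, c + 1] = True
        masked = type(target)(year=target.year, dates=target.dates.copy(),
                              bands=bands, valid_mask=valid)
        pot, skips = select_potential_samples(
            rec, stacks[2017], masked, feature_models)
        assert len(pot) == 1 and len(skips) == 0
        assert (pot["row"].iloc[0], pot["col"].iloc[0]) == (r + 1, c + 1)

    def test_all_neighbors_masked_skips(self, clean_scene, feature_models):
        stacks = clean_scene["stacks"]
        target = stacks[2018]
        rec = clean_scene["samples"].iloc[[0]]
        masked = type(target)(year=target.year, dates=target.dates.copy(),
                              bands=target.bands.copy(),
                              valid_mask=np.zeros_like(target.valid_mask))
        pot, skips = select_potential_samples(rec, stacks[2017], masked, feature_models)
        assert len(pot) == 0
        assert list(skips["id"]) == list(rec["id"])
        assert "no eligible neighbor" in skips["reason"].iloc[0]

    def test_even_window_rejected(self, clean_scene, feature_models):
        with pytest.raises(ContractError):
            select_potential_samples(clean_scene["samples"], clean_scene["stacks"][2017],
                                     clean_scene["stacks"][2018], feature_models, window=4)

    def test_potential_purity_high_without_rotation(self, small_scene, feature_models):
        pot, _ = select_potential_samples(
            small_scene["samples"], small_scene["stacks"][2017],
            small_scene["stacks"][2018], feature_models)
        assert purity(pot, small_scene["truth"], 2018) >= 0.9
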