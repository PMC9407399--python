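"""Case enumeration, stitching invariances, candidate maps, and the eta rule."""

import itertools

import numpy as np
import pytest

from entroseg.model import AneurysmSegNet, ModelConfig
from entroseg.phantom import LabeledVolume
from entroseg.recombine import (
    PatchGrid,
    RecombinationConfig,
    SegmentationResult,
    average_stitch,
    build_candidates,
    case_covers_row,
    count_configurations,
    decide_final,
    enumerate_row_cases,
    predict_grid,
    sample_and_average,
    segment_slice,
    segment_volume,
    stitch_configuration,
)
from entroseg.selection import SelectionParams, patch_grid_origins


@pytest.fixture(scope="module")
def grid_origins():
    return patch_grid_origins((256, 256), 96, 32)


def make_grid(probs, origins):
    return PatchGrid(np.asarray(probs, dtype=float), origins, (256, 256), 96)


class TestCaseEnumeration:
    def test_standard_geometry_has_seven_cases(self):
        assert len(enumerate_row_cases(6)) == 7

    def test_every_case_covers_the_row_extent(self):
        for case in enumerate_row_cases(6):
            assert case_covers_row(case, extent=256, window=96, stride=32)

    def test_pair_cases_are_exactly_the_interior_pairs(self):
        """Brute force: {0,5} + any 2 of {1,2,3,4} — all C(4,2) subsets, no more."""
        cases = enumerate_row_cases(6)
        pair_cases = {c for c in cases if len(c) == 4}
        expected = {
            (0, a, b, 5) for a, b in itertools.combinations(range(1, 5), 2)
        }
        assert pair_cases == expected
        assert tuple(range(6)) in cases

    def test_unsupported_geometry_rejected(self):
        with pytest.raises(ValueError):
            enumerate_row_cases(4)

    def test_total_configuration_count(self):
        assert count_configurations(6) == 14_749
        assert count_configurations(6) == 6 * 7**4 + 7**3  # arithmetic identity
        assert count_configurations(6) >= RecombinationConfig().n_samples


class TestStitching:
    def test_constant_patches_stitch_seamlessly(self, grid_origins):
        grid = make_grid(np.full((36, 96, 96), 0.4), grid_origins)
        for row_cases in ([0] * 6, [6] * 6, [3, 1, 4, 1, 5, 2]):
            out = stitch_configuration(grid, np.array(row_cases), np.array(row_cases))
            np.testing.assert_allclose(out, 0.4)

    def test_sample_and_average_constant_and_bounds(self, grid_origins, rng):
        grid = make_grid(np.full((36, 96, 96), 0.7), grid_origins)
        s = sample_and_average(grid, RecombinationConfig(seed=1))
        np.testing.assert_allclose(s, 0.7)
        grid2 = make_grid(rng.random((36, 96, 96)), grid_origins)
        s2 = sample_and_average(grid2, RecombinationConfig(seed=1))
        assert s2.min() >= 0.0 and s2.max() <= 1.0

    def test_single_sample_equals_its_stitched_map(self, grid_origins, rng):
        grid = make_grid(rng.random((36, 96, 96)), grid_origins)
        cfg = RecombinationConfig(n_samples=1, seed=5)
        s = sample_and_average(grid, cfg)
        gen = np.random.default_rng(cfg.seed)
        rows = gen.integers(0, 7, 6)
        cols = gen.integers(0, 7, 6)
        np.testing.assert_allclose(s, stitch_configuration(grid, rows, cols))

    def test_seeded_runs_identical(self, grid_origins, rng):
        grid = make_grid(rng.random((36, 96, 96)), grid_origins)
        a = sample_and_average(grid, RecombinationConfig(seed=9))
        b = sample_and_average(grid, RecombinationConfig(seed=9))
        np.testing.assert_array_equal(a, b)

    def test_average_strategy_agrees_on_constant_inputs(self, grid_origins):
        grid = make_grid(np.full((36, 96, 96), 0.25), grid_origins)
        np.testing.assert_allclose(average_stitch(grid), 0.25)
        np.testing.assert_allclose(
            average_stitch(grid),
            sample_and_average(grid, RecombinationConfig(seed=0)),
        )


class TestCandidates:
    def test_exactly_36_candidates_with_window_replacement(self, grid_origins, rng):
        grid = make_grid(rng.random((36, 96, 96)), grid_origins)
        s_aver = average_stitch(grid)
        cands = build_candidates(grid, s_aver)
        assert cands.shape == (36, 256, 256)
        for k, (r, c) in enumerate(grid.origins):
            np.testing.assert_array_equal(
                cands[k, r : r + 96, c : c + 96], grid.probs[k]
            )
            outside = cands[k].copy()
            outside[r : r + 96, c : c + 96] = s_aver[r : r + 96, c : c + 96]
            np.testing.assert_array_equal(outside, s_aver)

    def test_noop_replacement_preserves_s_aver(self, grid_origins):
        grid = make_grid(np.full((36, 96, 96), 0.6), grid_origins)
        s_aver = average_stitch(grid)
        cands = build_candidates(grid, s_aver)
        np.testing.assert_allclose(cands[7], s_aver)


class TestDecideFinal:
    def _candidates(self, n_with_fg, area_of_best=50):
        cands = np.zeros((36, 64, 64))
        for k in range(n_with_fg):
            size = area_of_best if k == 0 else 5
            cands[k, :1, :size] = 1.0
        return cands

    def test_truth_table_over_all_combinations(self):
        """Exhaustive check of the decision rule for (S_Aver empty?, n)."""
        cfg = RecombinationConfig(eta=33)
        for aver_has_fg in (False, True):
            s_aver = np.zeros((64, 64))
            if aver_has_fg:
                s_aver[0, 0] = 1.0
            for n in range(37):
                cands = self._candidates(n)
                res = decide_final(s_aver, cands, cfg)
                expect_accept = (aver_has_fg and n > 33) or (not aver_has_fg and n > 3)
                assert (res.decision == "averaged-candidate") == expect_accept
                if expect_accept:
                    # candidate 0 has the largest foreground area
                    np.testing.assert_array_equal(res.final_mask, cands[0] >= 0.5)
                else:
                    assert not res.final_mask.any()

    def test_vacuous_all_empty_case(self):
        res = decide_final(
            np.zeros((64, 64)), np.zeros((36, 64, 64)), RecombinationConfig()
        )
        assert res.decision == "empty" and not res.final_mask.any()


class _ConstantModel:
    """Stub emitting a fixed foreground probability for every patch."""

    def __init__(self, value):
        self.value = value

    def predict_proba(self, windows):
        w = np.asarray(windows)
        return np.full((w.shape[0],) + w.shape[2:], self.value)


@pytest.fixture(scope="module")
def volume256():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (5, 256, 256)).astype(np.float32)
    return LabeledVolume(img, np.zeros_like(img, dtype=np.uint8))


class TestGridPrediction:
    def test_grid_has_36_maps_with_matching_origins(self, volume256):
        grid = predict_grid(volume256, 2, _ConstantModel(0.0))
        assert len(grid.probs) == 36
        assert grid.origins == patch_grid_origins((256, 256), 96, 32)

    def test_zero_model_gives_zero_maps(self, volume256):
        grid = predict_grid(volume256, 2, _ConstantModel(0.0))
        assert not grid.probs.any()

    def test_segment_volume_zero_model_all_empty(self, volume256):
        mask, results = segment_volume(volume256, _ConstantModel(0.0))
        assert mask.shape == volume256.intensities.shape
        assert not mask.any()
        assert all(r.decision == "empty" for r in results)

    def test_segment_volume_composes_per_slice_chain(self, volume256):
        model = _ConstantModel(0.8)
        cfg = RecombinationConfig(seed=4)
        mask, results = segment_volume(volume256, model, config=cfg)
        manual = segment_slice(volume256, 3, model, config=cfg)
        np.testing.assert_array_equal(mask[3], manual.final_mask)
        np.testing.assert_allclose(results[3].s_aver, manual.s_aver)

    def test_nonstandard_geometry_falls_back_to_average(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (3, 128, 128)).astype(np.float32)
        vol = LabeledVolume(img, np.zeros_like(img, dtype=np.uint8))
        with pytest.warns(UserWarning):
            res = segment_slice(vol, 1, _ConstantModel(0.9))
        assert res.final_mask.all()  # constant 0.9 >= threshold everywhere
        assert res.candidates is None
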