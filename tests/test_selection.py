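"""Entropy scores against brute-force oracles; slice/patch/triplet selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entroseg.phantom import LabeledVolume, PhantomConfig, generate_phantom
from entroseg.selection import (
    SelectionParams,
    augment,
    extract_patches,
    flip_horizontal,
    generalized_range,
    gradient_entropy,
    gradient_y,
    load_triplets,
    normalize_slice,
    range_entropy,
    save_triplets,
    select_slices,
    select_triplets,
    shannon_entropy,
    _rotate45,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def entropy_oracle(region):
    """Brute-force histogram entropy over 256 integer bins."""
    vals = np.rint(np.asarray(region, dtype=float)).astype(int).ravel()
    total = 0.0
    for i in range(256):
        p = np.sum(vals == i) / vals.size
        if p > 0:
            total -= p * np.log2(p)
    return total


def range_oracle(slice_, b):
    flat = np.sort(np.asarray(slice_, dtype=float).ravel())
    return (flat[-b:].sum() - flat[:b].sum()) / b


def gradient_oracle(patch, c):
    patch = np.asarray(patch, dtype=float)
    diffs = sorted(
        patch[i, j] - patch[i, j - 1]
        for i in range(patch.shape[0])
        for j in range(1, patch.shape[1])
    )
    return float(np.mean(diffs[-c:]))


class TestNormalizeSlice:
    def test_constant_slice_maps_to_zeros(self):
        assert not normalize_slice(np.full((8, 8), 7.0)).any()

    def test_direct_evaluation_and_endpoints(self):
        s = np.array([[0.0, 50.0], [100.0, 25.0]])
        out = normalize_slice(s)
        assert out[0, 1] == pytest.approx(127.5)
        assert out[0, 0] == 0.0
        assert out[1, 0] == 255.0

    def test_output_range_and_idempotence(self, rng):
        s = rng.uniform(-40, 900, (32, 32))
        out = normalize_slice(s)
        assert out.min() >= 0.0 and out.max() <= 255.0
        np.testing.assert_allclose(normalize_slice(out), out, atol=1e-9)


class TestEntropyScores:
    def test_constant_region_zero_bits(self):
        assert shannon_entropy(np.full((6, 6), 42.0)) == 0.0

    def test_two_equal_bins_one_bit(self):
        region = np.concatenate([np.zeros(32), np.full(32, 255.0)])
        assert shannon_entropy(region) == pytest.approx(1.0)

    def test_entropy_matches_histogram_oracle(self, rng):
        region = rng.uniform(0, 255, (32, 32))
        assert shannon_entropy(region) == pytest.approx(entropy_oracle(region), abs=1e-12)

    def test_entropy_bounded_by_8_bits(self, rng):
        for _ in range(5):
            region = rng.uniform(0, 255, (16, 16))
            assert 0.0 <= shannon_entropy(region) <= 8.0

    def test_generalized_range_examples_and_oracle(self, rng):
        assert generalized_range(np.full((4, 4), 3.0), 2) == 0.0
        assert generalized_range(np.array([0.0, 10.0, 20.0, 30.0]), 2) == pytest.approx(20.0)
        s = rng.uniform(0, 255, (20, 20))
        assert generalized_range(s, 10) == pytest.approx(range_oracle(s, 10), abs=1e-9)

    def test_generalized_range_requires_enough_pixels(self):
        with pytest.raises(ValueError):
            generalized_range(np.zeros(4), 10)

    def test_range_entropy_composes_the_two_terms(self, rng):
        params = SelectionParams()
        s = rng.uniform(0, 255, (24, 24))
        expected = entropy_oracle(s) + params.w * range_oracle(s, params.b)
        assert range_entropy(s, params) == pytest.approx(expected, abs=1e-9)
        assert range_entropy(np.full((8, 8), 9.0), params) == 0.0
        assert range_entropy(s, SelectionParams(w=0.0)) == pytest.approx(
            shannon_entropy(s)
        )


class TestGradientScores:
    def test_constant_patch_zero(self):
        assert gradient_y(np.full((8, 8), 5.0), 4) == 0.0

    def test_uniform_column_ramp_returns_slope(self):
        patch = np.tile(np.arange(8.0) * 3.0, (8, 1))
        assert gradient_y(patch, 5) == pytest.approx(3.0)

    def test_gradient_matches_enumeration_oracle(self, rng):
        patch = rng.uniform(0, 255, (96, 96))
        assert gradient_y(patch, 20) == pytest.approx(gradient_oracle(patch, 20), abs=1e-9)

    def test_gradient_needs_enough_differences(self):
        with pytest.raises(ValueError):
            gradient_y(np.zeros((2, 2)), 10)

    def test_gradient_entropy_composes_and_reduces(self, rng):
        params = SelectionParams()
        patch = rng.uniform(0, 255, (32, 32))
        expected = entropy_oracle(patch) + params.gamma * gradient_oracle(patch, params.c)
        assert gradient_entropy(patch, params) == pytest.approx(expected, abs=1e-9)
        assert gradient_entropy(patch, SelectionParams(gamma=0.0)) == pytest.approx(
            shannon_entropy(patch)
        )

    def test_gradient_bonus_is_monotone(self, rng):
        """GH >= H whenever the top-c gradient mean is non-negative."""
        params = SelectionParams()
        for _ in range(10):
            patch = rng.uniform(0, 255, (16, 16))
            if gradient_y(patch, params.c) >= 0:
                assert gradient_entropy(patch, params) >= shannon_entropy(patch)


class TestSelectSlices:
    def _volume(self, intensities):
        arr = np.asarray(intensities, dtype=np.float32)
        return LabeledVolume(arr, np.zeros_like(arr, dtype=np.uint8))

    def test_keeps_seven_of_ten(self, rng):
        vol = self._volume(rng.uniform(0, 255, (10, 16, 16)))
        assert len(select_slices(vol, SelectionParams())) == 7

    def test_identical_slices_tie_break_to_first_seven(self, rng):
        base = rng.uniform(0, 255, (16, 16))
        vol = self._volume(np.stack([base] * 20))
        retained = select_slices(vol, SelectionParams())
        assert [s.index for s in retained] == [0, 1, 2, 3, 4, 5, 6, 10, 11, 12, 13, 14, 15, 16]

    def test_retained_set_matches_full_sort_oracle(self, rng):
        vol = self._volume(rng.uniform(0, 255, (10, 16, 16)))
        params = SelectionParams()
        retained = select_slices(vol, params)
        scores = [range_entropy(normalize_slice(vol.intensities[z]), params) for z in range(10)]
        expected = set(np.argsort(scores)[-7:])
        assert {s.index for s in retained} == expected
        assert [s.index for s in retained] == sorted(s.index for s in retained)

    def test_remainder_block_keeps_proportional_count(self, rng):
        vol = self._volume(rng.uniform(0, 255, (14, 16, 16)))
        retained = select_slices(vol, SelectionParams())
        # 7 from the full block, ceil(0.7*4)=3 from the remainder
        assert len(retained) == 10


class TestExtractPatches:
    def test_standard_slice_yields_36_patches(self):
        patches = extract_patches(np.zeros((256, 256)), 96, 32)
        assert len(patches) == 36
        assert patches[0].origin == (0, 0)
        assert patches[-1].origin == (160, 160)

    def test_window_equal_to_slice_is_single_patch(self):
        patches = extract_patches(np.zeros((96, 96)), 96, 32)
        assert len(patches) == 1 and patches[0].origin == (0, 0)

    def test_160_slice_yields_9_patches(self):
        assert len(extract_patches(np.zeros((160, 160)), 96, 32)) == 9

    def test_window_larger_than_slice_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((64, 64)), 96, 32)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        h=st.integers(8, 60),
        w=st.integers(8, 60),
        window=st.integers(2, 8),
        stride=st.integers(1, 6),
    )
    def test_patch_count_closed_form(self, h, w, window, stride):
        patches = extract_patches(np.zeros((h, w)), window, stride)
        expected = ((h - window) // stride + 1) * ((w - window) // stride + 1)
        assert len(patches) == expected
        for p in patches:
            r, c = p.origin
            assert r + window <= h and c + window <= w


class TestSelectTriplets:
    def test_top_k_saturation_returns_all_sorted(self, small_phantom):
        params = SelectionParams(top_k=10_000)
        with pytest.warns(UserWarning):
            trips = select_triplets(small_phantom, params=params)
        ghs = [t.center_gh for t in trips]
        assert ghs == sorted(ghs, reverse=True)
        # exhaustive: (retained - 2 centers) x 2x2 window grid
        retained = select_slices(small_phantom, params)
        n_windows = len(extract_patches(np.zeros((128, 128)), 96, 32))
        assert len(trips) == (len(retained) - 2) * n_windows

    def test_selected_dominate_excluded_by_gh(self, small_phantom):
        params = SelectionParams(top_k=8)
        selected = select_triplets(small_phantom, params=params)
        with pytest.warns(UserWarning):
            everything = select_triplets(
                small_phantom, params=SelectionParams(top_k=10_000)
            )
        worst_selected = min(t.center_gh for t in selected)
        excluded = everything[len(selected):]
        assert all(worst_selected >= t.center_gh for t in excluded)

    def test_channels_are_consecutive_retained_windows(self, small_phantom):
        params = SelectionParams(top_k=4)
        retained = select_slices(small_phantom, params)
        idx = [s.index for s in retained]
        for t in select_triplets(small_phantom, params=params):
            pos = idx.index(t.slice_index)
            r, c = t.origin
            for k, neighbour in enumerate((retained[pos - 1], retained[pos], retained[pos + 1])):
                np.testing.assert_array_equal(
                    t.channels[k], neighbour.values[r : r + 96, c : c + 96]
                )
            np.testing.assert_array_equal(
                t.target, small_phantom.mask[t.slice_index, r : r + 96, c : c + 96]
            )

    def test_round_trip_persistence(self, tmp_path, small_phantom):
        trips = select_triplets(small_phantom, params=SelectionParams(top_k=4))
        save_triplets(trips, tmp_path, "s1")
        back = load_triplets(tmp_path, "s1")
        assert len(back) == len(trips)
        np.testing.assert_allclose(back[0].channels, trips[0].channels, atol=0.5)
        assert back[0].origin == trips[0].origin


class TestAugment:
    def test_count_is_three_times_depth_over_three(self, small_phantom):
        out = augment(small_phantom, SelectionParams(), seed=0)
        assert len(out) == 3 * (small_phantom.shape[0] // 3)

    def test_nine_slices_give_nine_additional_inputs(self):
        vol = generate_phantom(
            PhantomConfig(depth=9, height=128, width=128, n_aneurysms=1, seed=7)
        )
        assert len(augment(vol, SelectionParams(), seed=1)) == 9

    def test_flip_is_involution(self, small_phantom):
        trips = augment(small_phantom, SelectionParams(), seed=0)[:2]
        for t in trips:
            back = flip_horizontal(flip_horizontal(t))
            np.testing.assert_array_equal(back.channels, t.channels)
            np.testing.assert_array_equal(back.target, t.target)

    def test_rotation_preserves_disk_area_within_tolerance(self):
        from entroseg.selection import PatchTriplet

        yy, xx = np.mgrid[:96, :96]
        disk = ((yy - 48) ** 2 + (xx - 48) ** 2 <= 20**2).astype(np.uint8)
        t = PatchTriplet(np.zeros((3, 96, 96)), disk, 0.0, 1, (0, 0))
        rot = _rotate45(t)
        assert abs(int(rot.target.sum()) - int(disk.sum())) / disk.sum() < 0.05

    def test_crop_identical_across_group_and_seeded(self, small_phantom):
        a = augment(small_phantom, SelectionParams(), seed=3)
        b = augment(small_phantom, SelectionParams(), seed=3)
        np.testing.assert_array_equal(a[0].channels, b[0].channels)
        c = augment(small_phantom, SelectionParams(), seed=4)
        assert any(
            x.origin != y.origin for x, y in zip(a, c)
        )


class TestClassImbalanceDirection:
    def test_gh_ranking_prefers_aneurysm_patches_over_plain_entropy(self):
        """Pooled over seeded sparse phantoms, GH selects more aneurysm patches."""
        gh_flags, h_flags = [], []
        for seed in (1, 2):
            vol = generate_phantom(
                PhantomConfig(depth=30, n_aneurysms=3, seed=seed)
            )
            gh = select_triplets(vol, params=SelectionParams(top_k=100))
            plain = select_triplets(vol, params=SelectionParams(gamma=0.0, top_k=100))
            gh_flags += [bool(t.target.any()) for t in gh]
            h_flags += [bool(t.target.any()) for t in plain]
        assert np.mean(gh_flags) > np.mean(h_flags)
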