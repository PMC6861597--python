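"""Normalization, enhancement, cropping, patch grid, selection, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segae.preprocess import (
    PatchSet,
    augment,
    crop_to_brain,
    enhance_with_pd,
    extract_patches,
    normalize_intensity,
    pad_to_patch,
    select_training_patches,
)


class TestNormalizeIntensity:
    def test_constant_volume(self):
        v = np.zeros((10, 10, 10))
        v[2:4] = 5.0
        out = normalize_intensity(v)
        assert np.all(out[v != 0] == 1.0)
        assert np.all(out[v == 0] == 0.0)

    def test_percentile_convention(self):
        v = np.zeros((10, 10, 10))
        v.ravel()[:100] = np.arange(1, 101)
        expected_divisor = np.percentile(np.arange(1, 101), 99)  # linear interp
        out = normalize_intensity(v)
        assert v.ravel()[99] / expected_divisor == pytest.approx(out.ravel()[99])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.zeros((5, 5, 5)))

    def test_reapplication_consistent(self, rng):
        v = np.abs(rng.standard_normal((12, 12, 12)))
        once = normalize_intensity(v)
        twice = normalize_intensity(once)
        p99 = np.percentile(once[once != 0], 99)
        assert np.allclose(twice, once / p99)


class TestEnhanceWithPd:
    def test_constant_pd_gives_zero(self, rng):
        orig = rng.random((6, 6, 6))
        pd = np.full((6, 6, 6), 3.0)
        assert np.all(enhance_with_pd(orig, pd) == 0.0)

    def test_toy_values(self):
        orig = np.array([[[2.0, 2.0]]])
        pd = np.array([[[0.0, 4.0]]])
        assert np.allclose(enhance_with_pd(orig, pd), [[[8.0, 0.0]]])

    def test_homogeneous_in_pd(self, rng):
        orig = rng.random((6, 6, 6))
        pd = rng.random((6, 6, 6))
        a = 2.5
        assert np.allclose(enhance_with_pd(orig, a * pd), a * enhance_with_pd(orig, pd))

    def test_linear_in_orig(self, rng):
        o1, o2 = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        pd = rng.random((5, 5, 5))
        assert np.allclose(
            enhance_with_pd(o1 + o2, pd),
            enhance_with_pd(o1, pd) + enhance_with_pd(o2, pd),
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enhance_with_pd(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


class TestCropToBrain:
    def test_single_voxel(self):
        v = np.zeros((1, 10, 12, 14))
        v[0, 3, 7, 9] = 1.0
        cropped, offset = crop_to_brain(v)
        assert cropped.shape == (1, 1, 1, 1)
        assert offset == (3, 7, 9)

    def test_full_support(self, rng):
        v = rng.random((2, 6, 6, 6)) + 0.1
        cropped, offset = crop_to_brain(v)
        assert cropped.shape == v.shape and offset == (0, 0, 0)

    def test_ellipsoid_bounds(self, small_phantom):
        truth, vols = small_phantom
        cropped, offset = crop_to_brain(vols)
        nz = np.argwhere(truth.brain_mask > 0)
        lo, hi = nz.min(axis=0), nz.max(axis=0)
        assert offset == tuple(lo)
        assert cropped.shape[1:] == tuple(hi - lo + 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            crop_to_brain(np.zeros((2, 5, 5, 5)))


class TestExtractPatches:
    def test_patch_equals_volume(self, rng):
        v = rng.random((2, 80, 80, 80))
        ps = extract_patches(v, (80, 80, 80), 40)
        assert len(ps) == 1 and tuple(ps.origins[0]) == (0, 0, 0)
        assert np.array_equal(ps.patches[0], v)

    @pytest.mark.parametrize(
        "length,expected",
        [(120, [0, 40]), (100, [0, 20]), (80, [0]), (81, [0, 1])],
    )
    def test_clamped_axis_origins(self, length, expected, rng):
        v = rng.random((1, length, 80, 80))
        ps = extract_patches(v, (80, 80, 80), 40)
        assert sorted(set(o[0] for o in ps.origins)) == expected

    def test_patches_are_copies(self, rng):
        v = rng.random((1, 80, 80, 80))
        ps = extract_patches(v, (80, 80, 80), 40)
        ps.patches[0, 0, 0, 0, 0] = -99
        assert v[0, 0, 0, 0] != -99

    def test_patches_match_source_subvolumes(self, rng):
        v = rng.random((2, 50, 44, 60))
        ps = extract_patches(v, (24, 24, 24), 16)
        for patch, (i, j, k) in zip(ps.patches, ps.origins):
            assert np.array_equal(patch, v[:, i : i + 24, j : j + 24, k : k + 24])

    def test_full_coverage(self, rng):
        v = rng.random((1, 50, 44, 60))
        ps = extract_patches(v, (24, 24, 24), 16)
        covered = np.zeros(v.shape[1:], bool)
        for i, j, k in ps.origins:
            covered[i : i + 24, j : j + 24, k : k + 24] = True
        assert covered.all()

    def test_invalid_stride_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((1, 24, 24, 24)), (24, 24, 24), 0)

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((1, 20, 24, 24)), (24, 24, 24), 8)

    def test_pad_to_patch_roundtrip(self, rng):
        v = rng.random((2, 20, 30, 24))
        padded, offs = pad_to_patch(v, (32, 32, 32))
        assert padded.shape[1:] == (32, 32, 32)
        d, h, w = v.shape[1:]
        assert np.array_equal(
            padded[:, offs[0] : offs[0] + d, offs[1] : offs[1] + h, offs[2] : offs[2] + w], v
        )


class TestSelectTrainingPatches:
    def test_all_ties_keep_first_half_in_origin_order(self, rng):
        v = rng.random((1, 80, 80, 80)) + 0.1  # no background at all
        ps = extract_patches(v, (40, 40, 40), 40)
        sel = select_training_patches(ps, 0.5)
        assert len(sel) == 4  # ceil(8/2)
        expected = sorted(map(tuple, ps.origins))[:4]
        assert [tuple(o) for o in sel.origins] == expected

    def test_fewest_background_wins(self):
        v = np.zeros((1, 80, 40, 40))
        v[0, :40] = 1.0  # first half fully brain
        v[0, 40:, :20] = 1.0  # second half: half background
        ps = extract_patches(v, (40, 40, 40), 40)
        sel = select_training_patches(ps, 0.5)
        assert [tuple(o) for o in sel.origins] == [(0, 0, 0)]

    def test_matches_bruteforce_sort(self, rng):
        v = (rng.random((2, 48, 48, 48)) > 0.6) * rng.random((2, 48, 48, 48))
        ps = extract_patches(v, (16, 16, 16), 16)
        sel = select_training_patches(ps, 0.4)
        # brute force: canonical origin order, then stable sort on background
        order = sorted(
            range(len(ps)),
            key=lambda i: (int(np.all(ps.patches[i] == 0, axis=0).sum()),),
        )
        counts = [int(np.all(p == 0, axis=0).sum()) for p in sel.patches]
        expected = sorted(
            int(np.all(ps.patches[i] == 0, axis=0).sum()) for i in order
        )[: len(sel)]
        assert sorted(counts) == expected

    def test_order_invariance(self, rng):
        v = (rng.random((1, 48, 48, 48)) > 0.5) * rng.random((1, 48, 48, 48))
        ps = extract_patches(v, (16, 16, 16), 16)
        perm = rng.permutation(len(ps))
        shuffled = PatchSet(ps.patches[perm], ps.origins[perm], ps.patch_size, ps.stride)
        a = select_training_patches(ps, 0.5)
        b = select_training_patches(shuffled, 0.5)
        assert np.array_equal(a.origins, b.origins)
        assert np.array_equal(a.patches, b.patches)

    def test_empty_rejected(self):
        ps = PatchSet(np.zeros((0, 1, 4, 4, 4)), np.zeros((0, 3), int), (4, 4, 4), 4)
        with pytest.raises(ValueError):
            select_training_patches(ps)


class TestAugment:
    def test_noop(self, rng):
        p = rng.random((3, 8, 8, 8))
        assert np.array_equal(augment(p, 0.0, 0.0, seed=1), p)

    def test_pure_channel_scaling_reproducible(self, rng):
        p = rng.random((3, 8, 8, 8))
        out = augment(p, 0.0, 0.5, seed=42)
        scales = np.random.default_rng(42).normal(1.0, 0.5, size=(3, 1, 1, 1))
        assert np.allclose(out, p * scales)

    def test_noise_standard_deviation(self):
        p = np.zeros((1, 50, 50, 40))
        out = augment(p, noise_sd=0.05, scale_sd=0.0, seed=3)
        assert out.std() == pytest.approx(0.05, abs=0.002)

    def test_determinism(self, rng):
        p = rng.random((2, 8, 8, 8))
        assert np.array_equal(augment(p, seed=9), augment(p, seed=9))

    def test_nonfinite_rejected(self):
        p = np.full((1, 4, 4, 4), np.nan)
        with pytest.raises(ValueError):
            augment(p)


@settings(max_examples=25, deadline=None)
@given(
    length=st.integers(min_value=16, max_value=64),
    patch=st.integers(min_value=8, max_value=16),
    stride=st.integers(min_value=4, max_value=16),
)
def test_patch_grid_covers_every_voxel(length, patch, stride):
    """Property: for stride <= patch the clamped grid leaves no voxel
    unsampled on any axis."""
    from hypothesis import assume

    assume(stride <= patch)
    v = np.ones((1, length, 16, 16))
    ps = extract_patches(v, (patch, 16, 16), stride)
    covered = np.zeros(length, bool)
    for o in ps.origins:
        covered[o[0] : o[0] + patch] = True
    assert covered.all()
    assert all(o[0] + patch <= length for o in ps.origins)
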