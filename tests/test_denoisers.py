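"""Denoiser family: block matching, collaborative filtering, aggregation,
nonlocal PCA, and the common registry contract."""

import numpy as np
import pytest

from pnpqsm.denoise import (
    DenoiserSpec,
    aggregate,
    block_match,
    collaborative_filter,
    denoise,
    registered_denoisers,
)
from pnpqsm.denoise.blockmatch import gather_groups, match_all
from pnpqsm.denoise.nlpca import nlpca_filter_group
from pnpqsm.volume import VolumeGrid


def psnr(clean, x):
    dr = clean.max() - clean.min()
    return 10 * np.log10(dr**2 / np.mean((x - clean) ** 2))


@pytest.fixture(scope="module")
def noisy_piecewise():
    from pnpqsm import PhantomSpec, make_phantom
    from pnpqsm.phantom import Inclusion

    chi, _, _ = make_phantom(
        PhantomSpec(
            shape=(64, 64, 64),
            inclusions=[
                Inclusion("sphere", (32, 32, 32), 14.0, 0.1, 1),
                Inclusion("cuboid", (14, 14, 14), (10, 10, 10), -0.05, 2),
                Inclusion("ellipsoid", (48, 20, 44), (8, 6, 7), 0.05, 3),
            ],
        )
    )
    clean = chi.data
    rng = np.random.default_rng(99)
    sigma = 0.02
    return clean, clean + rng.normal(0, sigma, clean.shape), sigma


class TestRegistry:
    def test_constant_volume_fixed_point_every_denoiser(self):
        const = VolumeGrid(np.full((20, 20, 20), 0.25))
        for name in registered_denoisers():
            out = denoise(const, DenoiserSpec(name=name, sigma=0.05))
            np.testing.assert_allclose(out.data, 0.25, atol=1e-10)

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="bm4d"):
            denoise(VolumeGrid(np.zeros((8, 8, 8))), DenoiserSpec(name="nope", sigma=1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            DenoiserSpec(name="bm4d", sigma=-1.0)
        with pytest.raises(ValueError):
            denoise(VolumeGrid(np.zeros((8, 8, 8))), DenoiserSpec(name="bm4d", sigma=None))

    def test_determinism(self, noisy_piecewise):
        _, noisy, sigma = noisy_piecewise
        spec = DenoiserSpec(name="bm4d", sigma=sigma)
        a = denoise(VolumeGrid(noisy), spec).data
        b = denoise(VolumeGrid(noisy), spec).data
        np.testing.assert_array_equal(a, b)

    def test_gaussian_small_width_is_identity(self, rng):
        x = VolumeGrid(rng.normal(size=(16, 16, 16)))
        out = denoise(x, DenoiserSpec(name="gaussian", sigma=1e-8))
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_monotone_benefit_and_bm4d_beats_slices(self, noisy_piecewise):
        clean, noisy, sigma = noisy_piecewise
        base = psnr(clean, noisy)
        gains = {}
        for name in ("nlm", "bm3d_slices", "bm4d", "nlpca"):
            out = denoise(VolumeGrid(noisy), DenoiserSpec(name=name, sigma=sigma))
            gains[name] = psnr(clean, out.data)
            assert gains[name] > base, name
        assert gains["bm4d"] >= gains["bm3d_slices"]

    def test_mask_external_voxels_untouched(self, noisy_piecewise):
        _, noisy, sigma = noisy_piecewise
        mask = np.zeros(noisy.shape, dtype=np.uint8)
        mask[8:40, 8:40, 8:40] = 1
        vol = VolumeGrid(noisy, mask=mask)
        out = denoise(vol, DenoiserSpec(name="bm4d", sigma=sigma))
        far = np.zeros_like(mask, dtype=bool)
        far[50:, 50:, 50:] = True  # beyond the padded bounding box
        np.testing.assert_array_equal(out.data[far], noisy[far])


class TestBlockMatch:
    def test_planted_copies_found(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        patch = rng.normal(size=(4, 4, 4))
        corners = [(2, 2, 2), (2, 6, 2), (6, 2, 6)]
        for c in corners:
            vol[c[0] : c[0] + 4, c[1] : c[1] + 4, c[2] : c[2] + 4] = patch
        spec = DenoiserSpec(name="bm4d", sigma=1.0, patch_size=4, search_radius=5, max_group_size=3)
        found = block_match(vol, corners[0], spec)
        assert set(found) == set(corners)

    def test_group_of_one(self, rng):
        vol = rng.normal(size=(12, 12, 12))
        spec = DenoiserSpec(name="bm4d", sigma=1.0, max_group_size=1)
        assert block_match(vol, (4, 4, 4), spec) == [(4, 4, 4)]

    def test_constant_volume_lexicographic_ties(self):
        vol = np.zeros((12, 12, 12))
        spec = DenoiserSpec(name="bm4d", sigma=1.0, patch_size=4, search_radius=2, max_group_size=4)
        found = block_match(vol, (4, 4, 4), spec)
        assert found[0] == (4, 4, 4)
        assert found[1:] == [(2, 2, 2), (2, 2, 3), (2, 2, 4)]

    def test_patch_larger_than_volume(self):
        spec = DenoiserSpec(name="bm4d", sigma=1.0, patch_size=8)
        with pytest.raises(ValueError):
            block_match(np.zeros((4, 4, 4)), (0, 0, 0), spec)

    def test_fast_matcher_agrees_with_reference(self, rng):
        """match_all distances/selections match brute-force block_match."""
        vol = rng.normal(size=(14, 14, 14))
        spec = DenoiserSpec(
            name="bm4d", sigma=1.0, patch_size=4, search_radius=2, max_group_size=4, stride=3
        )
        refs, offsets, sel = match_all(vol, spec)
        for i in range(0, refs.shape[0], 7):
            ref = tuple(refs[i])
            fast_corners = [tuple(refs[i] + offsets[j]) for j in sel[i]]
            exact = block_match(vol, ref, spec)
            assert fast_corners[0] == ref
            # same set of corners up to distance ties
            d_exact = sorted(
                np.mean((vol[tuple(slice(c0, c0 + 4) for c0 in c)] -
                         vol[tuple(slice(c0, c0 + 4) for c0 in ref)]) ** 2)
                for c in exact
            )
            d_fast = sorted(
                np.mean((vol[tuple(slice(c0, c0 + 4) for c0 in c)] -
                         vol[tuple(slice(c0, c0 + 4) for c0 in ref)]) ** 2)
                for c in fast_corners
            )
            np.testing.assert_allclose(d_fast, d_exact, atol=1e-5)


class TestCollaborativeFilter:
    def test_constant_group_unchanged_dc_only(self):
        spec = DenoiserSpec(name="bm4d", sigma=0.1)
        group = np.full((4, 4, 4, 4), 3.0)
        out, weight = collaborative_filter(group, spec)
        np.testing.assert_allclose(out, 3.0, atol=1e-12)
        assert weight == pytest.approx(1.0 / 2.0)  # only DC retained

    def test_huge_sigma_collapses_to_dc(self, rng):
        spec = DenoiserSpec(name="bm4d", sigma=1e12)
        group = rng.normal(size=(3, 4, 4, 4))
        out, _ = collaborative_filter(group, spec)
        np.testing.assert_allclose(out, group.mean(), atol=1e-6)

    def test_energy_non_increasing(self, rng):
        spec = DenoiserSpec(name="bm4d", sigma=0.5)
        group = rng.normal(size=(4, 4, 4, 4))
        out, _ = collaborative_filter(group, spec)
        assert np.sum(out**2) <= np.sum(group**2) + 1e-10


class TestAggregate:
    def test_identity_filtering_partition_of_unity(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        spec = DenoiserSpec(name="bm4d", sigma=1.0, patch_size=4, search_radius=2, max_group_size=4)
        refs, offsets, sel = match_all(vol, spec)
        groups, corners = gather_groups(vol, refs, offsets, sel, 4)
        out = aggregate(groups, corners, np.ones(len(groups)), vol.shape)
        np.testing.assert_allclose(out, vol, atol=1e-10)

    def test_single_patch_whole_volume(self, rng):
        patch = rng.normal(size=(6, 6, 6))
        out = aggregate(
            [patch[None]], [np.zeros((1, 3), dtype=int)], [1.0], (6, 6, 6)
        )
        np.testing.assert_allclose(out, patch, atol=1e-12)

    def test_equal_weight_overlap_is_mean(self):
        p1 = np.zeros((1, 2, 2, 2))
        p2 = np.ones((1, 2, 2, 2))
        out = aggregate(
            [p1, p2],
            [np.array([[0, 0, 0]]), np.array([[0, 0, 0]])],
            [0.5, 0.5],
            (2, 2, 2),
        )
        np.testing.assert_allclose(out, 0.5)


class TestNlpca:
    def test_rank_one_population_recovered(self, rng):
        base = rng.normal(size=64)
        coeffs = rng.uniform(0.5, 1.5, size=8)
        group = (coeffs[:, None] * base[None, :]).reshape(8, 4, 4, 4)
        noisy = group + rng.normal(0, 0.01, group.shape)
        out, _ = nlpca_filter_group(noisy, sigma=0.01)
        s = np.linalg.svd(out.reshape(8, -1), compute_uv=False)
        assert s[1] < 0.05 * s[0]

    def test_tiny_sigma_keeps_everything(self, rng):
        group = rng.normal(size=(6, 4, 4, 4))
        out, _ = nlpca_filter_group(group, sigma=1e-12)
        np.testing.assert_allclose(out, group, atol=1e-8)

    def test_single_patch_passthrough(self, rng):
        group = rng.normal(size=(1, 4, 4, 4))
        out, w = nlpca_filter_group(group, sigma=0.1)
        np.testing.assert_array_equal(out, group)
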