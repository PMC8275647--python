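"""Sphere ROIs, Fisher z, seed maps, group tests, cluster inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocardiac.connectivity import (
    SeedCorrelation,
    _label_clusters,
    cluster_threshold,
    fisher_z,
    group_ttest,
    seed_fc_map,
    sphere_roi,
)
from neurocardiac.nuisance import _default_affine

from conftest import make_bold


def brute_force_sphere_count(radius_mm, voxel_mm):
    """Independent lattice enumeration: |{v : ||v*voxel|| <= r}|."""
    k = int(np.ceil(radius_mm / voxel_mm))
    count = 0
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            for l in range(-k, k + 1):
                if (i * i + j * j + l * l) * voxel_mm**2 <= radius_mm**2 + 1e-9:
                    count += 1
    return count


class TestSphereROI:
    @pytest.mark.parametrize("radius", [1.0, 5.0, 10.0])
    def test_voxel_count_matches_lattice_oracle(self, radius, small_grid_affine):
        roi = sphere_roi((0, 0, 0), radius, (21, 21, 21), small_grid_affine)
        assert roi.n_voxels == brute_force_sphere_count(radius, 2.5)

    def test_study_sphere_sizes(self, small_grid_affine):
        seed = sphere_roi((0, 0, 0), 10.0, (21, 21, 21), small_grid_affine)
        parcel = sphere_roi((0, 0, 0), 5.0, (21, 21, 21), small_grid_affine)
        assert seed.n_voxels == 257
        assert parcel.n_voxels == 33

    def test_all_members_within_radius(self, small_grid_affine):
        roi = sphere_roi((1.0, -2.0, 0.5), 7.5, (21, 21, 21), small_grid_affine)
        xyz = roi.indices @ small_grid_affine[:3, :3].T + small_grid_affine[:3, 3]
        assert np.all(np.linalg.norm(xyz - np.array([1.0, -2.0, 0.5]), axis=1) <= 7.5 + 1e-6)

    def test_empty_sphere_rejected(self, small_grid_affine):
        with pytest.raises(ValueError, match="empty sphere"):
            sphere_roi((500, 500, 500), 1.0, (21, 21, 21), small_grid_affine)


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)
        assert fisher_z(-0.5) == pytest.approx(-0.5493, abs=5e-5)

    def test_clamped_at_unity(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(z=st.floats(min_value=-7.9, max_value=7.9))
    def test_inverse_of_tanh(self, z):
        assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-9)


class TestSeedMap:
    def _bold_with_seed(self, rng, n=500):
        seed_ts = rng.normal(0, 1, n)
        data = rng.normal(0, 1, (5, 5, 5, n))
        data[2, 2, 2] = seed_ts  # single-voxel sphere at the grid center
        return make_bold(data), seed_ts

    def test_self_correlation_clamped(self, rng, small_grid_affine):
        bold, seed_ts = self._bold_with_seed(rng)
        roi = sphere_roi((0, 0, 0), 1.0, (5, 5, 5), _default_affine((5, 5, 5)))
        zmap = seed_fc_map(bold, roi)
        assert zmap.values[2, 2, 2] == pytest.approx(np.arctanh(1 - 1e-6))
        assert zmap.clamped[2, 2, 2]

    def test_independent_noise_voxel_near_zero(self, rng):
        bold, _ = self._bold_with_seed(rng, n=500)
        roi = sphere_roi((0, 0, 0), 1.0, (5, 5, 5), _default_affine((5, 5, 5)))
        zmap = seed_fc_map(bold, roi)
        others = np.delete(zmap.values.ravel(), np.ravel_multi_index((2, 2, 2), (5, 5, 5)))
        assert np.abs(others).max() < 0.25  # ~5 sigma of 1/sqrt(n-3)

    def test_planted_correlation_recovered(self, rng):
        n = 2000
        seed_ts = rng.normal(0, 1, n)
        r = 0.5
        voxel = r * seed_ts + np.sqrt(1 - r**2) * rng.normal(0, 1, n)
        data = rng.normal(0, 1, (3, 3, 3, n))
        data[1, 1, 1] = seed_ts
        data[0, 0, 0] = voxel
        roi = sphere_roi((0, 0, 0), 1.0, (3, 3, 3), _default_affine((3, 3, 3)))
        zmap = seed_fc_map(make_bold(data), roi)
        assert zmap.values[0, 0, 0] == pytest.approx(0.549, abs=3 / np.sqrt(n - 3))

    def test_constant_seed_rejected(self):
        data = np.zeros((3, 3, 3, 50))
        roi = sphere_roi((0, 0, 0), 1.0, (3, 3, 3), _default_affine((3, 3, 3)))
        with pytest.raises(ValueError, match="constant"):
            seed_fc_map(make_bold(data), roi)

    def test_zero_variance_voxel_flagged_undefined(self, rng):
        data = rng.normal(0, 1, (3, 3, 3, 100))
        data[0, 1, 2] = 5.0  # constant voxel
        roi = sphere_roi((0, 0, 0), 1.0, (3, 3, 3), _default_affine((3, 3, 3)))
        zmap = seed_fc_map(make_bold(data), roi)
        assert np.isnan(zmap.values[0, 1, 2]) and zmap.undefined[0, 1, 2]

    def test_estimator_fit_sets_attributes(self, rng):
        bold, _ = self._bold_with_seed(rng, n=100)
        est = SeedCorrelation(center=(0, 0, 0), radius=1.0)
        est.fit(bold)
        assert est.z_map_.values.shape == (5, 5, 5)
        assert est.seed_.n_voxels == 1


class TestGroupTTest:
    def test_paired_identical_maps_give_zero(self, rng):
        maps = [rng.normal(0, 1, (4, 4, 4)) for _ in range(5)]
        stat = group_ttest(maps, design="paired", maps_b=[m.copy() for m in maps])
        assert np.allclose(stat.t, 0.0)

    def test_one_sample_hand_value(self):
        maps = [np.full((2, 2), v) for v in (1.0, 2.0, 3.0, 4.0)]
        stat = group_ttest(maps, design="one_sample")
        assert stat.df == 3
        assert np.allclose(stat.t, 3.873, atol=5e-4)

    def test_paired_equals_one_sample_on_differences(self, rng):
        a = [rng.normal(0, 1, (3, 3)) for _ in range(6)]
        b = [rng.normal(0, 1, (3, 3)) for _ in range(6)]
        paired = group_ttest(a, design="paired", maps_b=b)
        diffs = [x - y for x, y in zip(a, b)]
        one = group_ttest(diffs, design="one_sample")
        assert np.array_equal(paired.t, one.t)
        assert paired.df == one.df

    def test_two_sample_degenerate_shift_flagged(self):
        a = [np.full((2,), 1.0)] * 4
        b = [np.full((2,), 3.0)] * 4
        stat = group_ttest(a, design="two_sample", maps_b=b)
        assert np.all(np.isinf(stat.t)) and np.all(stat.t < 0)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            group_ttest([rng.normal(0, 1, (2,)) for _ in range(2)])


def flood_fill_extents(mask):
    """Independent BFS flood-fill oracle for face-connected components."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    extents = []
    offsets = []
    for ax in range(mask.ndim):
        for d in (-1, 1):
            off = [0] * mask.ndim
            off[ax] = d
            offsets.append(tuple(off))
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack, size = [start], 0
        visited[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        extents.append(size)
    return sorted(extents)


class TestClusterInference:
    def test_labeling_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((12, 12, 12)) < 0.25
            labels, n = _label_clusters(mask)
            got = sorted(np.bincount(labels.ravel())[1:].tolist()) if n else []
            assert got == flood_fill_extents(mask)

    def test_planted_cube_detected(self, rng):
        n_sub, shape = 15, (12, 12, 12)
        effect = np.zeros(shape)
        effect[4:8, 4:8, 4:8] = 1.5
        maps = [effect + rng.normal(0, 1, shape) for _ in range(n_sub)]
        stat = cluster_threshold(group_ttest(maps), n_perm=200, seed=3)
        sig = [c for c in stat.clusters if c.p_corrected < 0.05]
        assert sig
        cube = {(i, j, k) for i in range(4, 8) for j in range(4, 8) for k in range(4, 8)}
        found = {tuple(v) for c in sig for v in c.voxels}
        assert len(found & cube) >= len(cube) / 2

    def test_isolated_voxel_not_significant(self, rng):
        n_sub, shape = 10, (10, 10, 10)
        maps = [rng.normal(0, 1, shape) for _ in range(n_sub)]
        stat = cluster_threshold(group_ttest(maps), n_perm=200, seed=4)
        for c in stat.clusters:
            if c.extent == 1:
                assert c.p_corrected > 0.3

    def test_no_suprathreshold_voxels_is_empty_not_error(self):
        maps = [np.full((3, 3), v) for v in (0.01, -0.01, 0.02, -0.02, 0.0)]
        stat = cluster_threshold(group_ttest(maps), n_perm=100, seed=0)
        assert stat.clusters == []

    def test_fdr_correction_orders_like_fwe(self, rng):
        n_sub, shape = 12, (14, 14, 1)
        effect = np.zeros(shape)
        effect[2:8, 2:8, 0] = 1.2
        effect[10:12, 10:12, 0] = 1.2
        maps = [effect + rng.normal(0, 1, shape) for _ in range(n_sub)]
        base = group_ttest(maps)
        fwe = cluster_threshold(base, n_perm=200, seed=1, correction="fwe")
        fdr = cluster_threshold(base, n_perm=200, seed=1, correction="fdr")
        assert len(fwe.clusters) == len(fdr.clusters)
        # BH-adjusted p never below the raw permutation p for the top cluster
        assert fdr.clusters[0].p_corrected >= fwe.clusters[0].p_corrected - 1e-12
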