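"""Connectome construction and the network-based statistic."""

import numpy as np
import pytest

from neurocardiac.network import (
    ConnectivityMatrix,
    NetworkBasedStatistic,
    Parcellation,
    connectivity_matrix,
    edgewise_ttest,
    nbs,
    parcel_timeseries,
    suprathreshold_components,
)
from neurocardiac.synthetic import (
    SimConfig,
    gen_coordinates,
    gen_paired_connectomes,
    random_connected_effect,
)

from conftest import make_bold


def _parcellation(n=4, spacing=30.0):
    centers = np.zeros((n, 3))
    centers[:, 0] = spacing * np.arange(n)
    return Parcellation([f"n{i}" for i in range(n)], centers)


def _cohort_from_edges(edge_stacks, n_nodes):
    """Build ConnectivityMatrix list from (n_sub, n_edges) upper-tri values."""
    iu = np.triu_indices(n_nodes, k=1)
    out = []
    for vals in edge_stacks:
        z = np.zeros((n_nodes, n_nodes))
        z[iu] = vals
        z[(iu[1], iu[0])] = vals
        valid = np.ones((n_nodes, n_nodes), dtype=bool)
        np.fill_diagonal(valid, False)
        out.append(ConnectivityMatrix(z=z, valid=valid))
    return out


class TestParcellation:
    def test_close_centers_warn(self):
        with pytest.warns(UserWarning, match="10 mm"):
            _parcellation(3, spacing=8.0)

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        labels, centers = gen_coordinates(SimConfig(seed=3, n_conn_nodes=30))
        path = tmp_path / "coords.tsv"
        pd.DataFrame({"label": labels, "x": centers[:, 0], "y": centers[:, 1],
                      "z": centers[:, 2]}).to_csv(path, sep="\t", index=False)
        parc = Parcellation.from_tsv(path)
        assert parc.n_nodes == 30
        assert np.allclose(parc.centers, centers, atol=1e-6)

    def test_generated_coordinates_respect_spacing(self):
        _, centers = gen_coordinates(SimConfig(seed=5, n_conn_nodes=60))
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        off = d[~np.eye(60, dtype=bool)]
        assert off.min() >= 10.0


class TestParcelTimeseries:
    def test_single_voxel_parcel_equals_voxel(self, rng):
        data = rng.normal(0, 1, (9, 9, 9, 40))
        bold = make_bold(data)
        # parcel centered exactly on voxel (4,4,4) = mm (0,0,0); tiny radius
        parc = Parcellation(["a", "b"], [[0, 0, 0], [0, 0, 10]], radius=1.0)
        ts, empty = parcel_timeseries(bold, parc)
        assert not empty.any()
        assert np.allclose(ts[0], data[4, 4, 4])

    def test_uniform_image_gives_constant_series(self):
        bold = make_bold(np.full((9, 9, 9, 30), 3.7))
        ts, _ = parcel_timeseries(bold, _parcellation(2, spacing=10.0))
        assert np.allclose(ts[~np.isnan(ts)], 3.7)

    def test_planted_source_correlation_recovered(self, rng):
        n = 400
        s1, s2 = rng.normal(0, 1, (2, n))
        r = 0.6
        s2 = r * s1 + np.sqrt(1 - r**2) * s2
        data = np.zeros((9, 9, 9, n))
        data[2, 4, 4] = s1 + 0.05 * rng.normal(0, 1, n)
        data[6, 4, 4] = s2 + 0.05 * rng.normal(0, 1, n)
        data += 1e-8 * rng.normal(0, 1, data.shape)
        bold = make_bold(data)
        parc = Parcellation(["a", "b"], [[-5, 0, 0], [5, 0, 0]], radius=1.0)
        ts, _ = parcel_timeseries(bold, parc)
        assert np.corrcoef(ts)[0, 1] == pytest.approx(r, abs=0.1)


class TestConnectivityMatrix:
    def test_edge_count_formula(self, rng):
        n = 260
        ts = rng.normal(0, 1, (n, 40))
        cm = connectivity_matrix(ts)
        assert int(np.triu(cm.valid, k=1).sum()) == n * (n - 1) // 2 == 33670

    def test_distance_mask(self, rng):
        centers = np.array([[0, 0, 0], [0, 0, 15], [0, 0, 40]])
        parc = Parcellation(["a", "b", "c"], centers)
        cm = connectivity_matrix(rng.normal(0, 1, (3, 50)), parc)
        assert not cm.valid[0, 1]  # 15 mm < 20 mm
        assert cm.valid[0, 2] and cm.valid[1, 2]  # 40 and 25 mm

    def test_symmetric(self, rng):
        cm = connectivity_matrix(rng.normal(0, 1, (5, 60)))
        assert np.array_equal(np.nan_to_num(cm.z), np.nan_to_num(cm.z.T))

    def test_constant_node_flagged(self, rng):
        ts = rng.normal(0, 1, (4, 50))
        ts[2] = 1.0
        cm = connectivity_matrix(ts)
        assert not cm.valid[2].any() and not cm.valid[:, 2].any()

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError, match="30 time points"):
            connectivity_matrix(rng.normal(0, 1, (4, 20)))


class TestEdgewiseTTest:
    def test_identical_cohorts_give_zero(self, rng):
        a = _cohort_from_edges(rng.normal(0, 1, (5, 6)), 4)
        t = edgewise_ttest(a, [ConnectivityMatrix(m.z.copy(), m.valid.copy()) for m in a])
        iu = np.triu_indices(4, 1)
        assert np.allclose(t[iu], 0.0)

    def test_hand_computed_edge_t(self):
        diffs = np.zeros((4, 6))
        diffs[:, 2] = [1, 2, 3, 4]
        base = np.arange(24, dtype=float).reshape(4, 6) / 10
        a = _cohort_from_edges(base + diffs, 4)
        b = _cohort_from_edges(base, 4)
        t = edgewise_ttest(a, b, design="paired")
        iu = np.triu_indices(4, 1)
        assert t[iu][2] == pytest.approx(3.873, abs=5e-4)
        assert np.allclose(np.delete(t[iu], 2), 0.0)

    def test_swapping_cohorts_negates(self, rng):
        a = _cohort_from_edges(rng.normal(0, 1, (6, 10)), 5)
        b = _cohort_from_edges(rng.normal(0, 1, (6, 10)), 5)
        t_ab = edgewise_ttest(a, b, design="paired")
        t_ba = edgewise_ttest(b, a, design="paired")
        iu = np.triu_indices(5, 1)
        assert np.allclose(t_ab[iu], -t_ba[iu])


def union_find_components(edges, n_nodes):
    """Independent union-find oracle: returns sorted component edge counts."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    counts = {}
    for i, j in edges:
        counts[find(i)] = counts.get(find(i), 0) + 1
    return sorted(counts.values())


class TestComponents:
    def test_two_components_by_inspection(self):
        t = np.zeros((6, 6))
        for i, j in [(1, 2), (2, 3), (4, 5)]:
            t[i, j] = t[j, i] = 5.0
        comps = suprathreshold_components(t, threshold=4.17)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == (1, 2, 3)
        assert comps[1].nodes == (4, 5)

    def test_tree_component_is_acyclic(self, rng):
        edges = random_connected_effect(60, 33, rng)
        t = np.zeros((60, 60))
        for i, j in edges:
            t[i, j] = t[j, i] = 6.0
        comps = suprathreshold_components(t)
        assert len(comps) == 1
        assert comps[0].extent == 33
        assert len(comps[0].nodes) == 34  # edges = nodes - 1: a tree

    def test_threshold_above_max_gives_empty(self, rng):
        t = np.abs(rng.normal(0, 1, (8, 8)))
        t = (t + t.T) / 2
        assert suprathreshold_components(t, threshold=100.0) == []

    def test_matches_union_find_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 50))
            density = rng.uniform(0.01, 0.15)
            t = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            on = rng.random(iu[0].size) < density
            t[iu[0][on], iu[1][on]] = 5.0
            t = t + t.T
            comps = suprathreshold_components(t, threshold=4.0)
            got = sorted(c.extent for c in comps)
            edges = list(zip(iu[0][on], iu[1][on]))
            assert got == union_find_components(edges, n)


def exhaustive_nbs_oracle(diffs, n_nodes, threshold):
    """Brute-force enumeration of all sign flips for the paired NBS null.

    Independent of the package path: plain loops, scipy-free t formula,
    union-find components.
    """
    n_sub, n_edges = diffs.shape
    iu = np.triu_indices(n_nodes, 1)

    def t_stats(d):
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        out = np.zeros(n_edges)
        for e in range(n_edges):
            out[e] = m[e] / (sd[e] / np.sqrt(n_sub)) if sd[e] > 0 else 0.0
        return out

    def max_extent(tv):
        edges = [(int(iu[0][e]), int(iu[1][e])) for e in range(n_edges) if tv[e] > threshold]
        sizes = union_find_components(edges, n_nodes)
        return max(sizes) if sizes else 0

    null_max = []
    for code in range(2**n_sub):
        signs = np.array([1.0 if (code >> k) & 1 else -1.0 for k in range(n_sub)])
        null_max.append(max_extent(t_stats(signs[:, None] * diffs)))
    null_max = np.array(null_max)

    t_obs = t_stats(diffs)
    obs_edges = [(int(iu[0][e]), int(iu[1][e])) for e in range(n_edges) if t_obs[e] > threshold]
    extents = union_find_components(obs_edges, n_nodes)
    return sorted(
        (ext, float((null_max >= ext).sum()) / null_max.size) for ext in extents
    )


class TestNBS:
    def test_exhaustive_enumeration_matches_oracle(self, rng):
        n_sub, n_nodes = 8, 6
        iu = np.triu_indices(n_nodes, 1)
        diffs = rng.normal(0.4, 1.0, (n_sub, iu[0].size))
        a = _cohort_from_edges(np.zeros((n_sub, iu[0].size)) + diffs, n_nodes)
        b = _cohort_from_edges(np.zeros((n_sub, iu[0].size)), n_nodes)
        res = nbs(a, b, design="paired", threshold=2.0, exhaustive=True, seed=0)
        got = sorted((c.extent, c.fwe_p) for c in res.components)
        expected = exhaustive_nbs_oracle(diffs, n_nodes, threshold=2.0)
        assert len(got) == len(expected)
        for (ge, gp), (ee, ep) in zip(got, expected):
            assert ge == ee
            assert gp == pytest.approx(ep, abs=1e-12)

    def test_fwe_p_monotone_in_extent(self, rng):
        # two planted components of different sizes in one cohort
        n_nodes, n_sub = 20, 10
        iu = np.triu_indices(n_nodes, 1)
        pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
        diffs = rng.normal(0, 0.1, (n_sub, iu[0].size))
        big = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
        small = [(10, 11)]
        for e in big + small:
            diffs[:, pos[e]] += 1.0
        a = _cohort_from_edges(diffs, n_nodes)
        b = _cohort_from_edges(np.zeros_like(diffs), n_nodes)
        res = nbs(a, b, design="paired", threshold=3.0, n_perm=300, seed=2)
        if len(res.components) >= 2:
            exts = [c.extent for c in res.components]
            ps = [c.fwe_p for c in res.components]
            order = np.argsort(exts)[::-1]
            assert all(
                ps[order[k]] <= ps[order[k + 1]] + 1e-12 for k in range(len(order) - 1)
            )

    def test_groups_analyzed_separately_are_independent(self):
        cfg_a = SimConfig(seed=21, n_conn_nodes=30, n_subjects=8, effect_size=2.0,
                          n_effect_edges=6)
        cfg_b = SimConfig(seed=22, n_conn_nodes=30, n_subjects=8, effect_size=0.0)
        t1a, t2a, _ = gen_paired_connectomes(cfg_a)
        t1b, t2b, _ = gen_paired_connectomes(cfg_b)
        res_a = nbs(t2a, t1a, design="paired", threshold=3.0, n_perm=200, seed=1)
        res_b = nbs(t2b, t1b, design="paired", threshold=3.0, n_perm=200, seed=1)
        assert res_a.components  # strong planted effect found
        # rerunning group A with group B present anywhere changes nothing
        res_a2 = nbs(t2a, t1a, design="paired", threshold=3.0, n_perm=200, seed=1)
        assert [c.fwe_p for c in res_a.components] == [c.fwe_p for c in res_a2.components]

    def test_strong_planted_tree_recovered(self):
        cfg = SimConfig(seed=31, n_conn_nodes=60, n_subjects=15, effect_size=3.0,
                        n_effect_edges=20)
        rng = np.random.default_rng(7)
        effect = random_connected_effect(60, 20, rng)
        t1, t2, truth = gen_paired_connectomes(cfg, effect_edges=effect)
        res = nbs(t2, t1, design="paired", n_perm=500, seed=3)  # default t > 4.17
        assert res.significant
        found = {e for c in res.significant for e in c.edges}
        planted = set(truth["effect_edges"])
        assert planted <= found
        assert len(found) <= len(planted) + 5  # few incidental null edges

    def test_estimator_wrapper(self):
        cfg = SimConfig(seed=41, n_conn_nodes=20, n_subjects=8, effect_size=2.5,
                        n_effect_edges=5)
        t1, t2, _ = gen_paired_connectomes(cfg)
        est = NetworkBasedStatistic(threshold=3.0, n_perm=200, seed=5)
        est.fit(t2, t1)
        assert est.t_matrix_.shape == (20, 20)
        assert est.result_.n_perm == 200
        assert est.get_params()["threshold"] == 3.0

    def test_reproducible_given_seed(self):
        cfg = SimConfig(seed=51, n_conn_nodes=25, n_subjects=8, effect_size=1.0)
        t1, t2, _ = gen_paired_connectomes(cfg)
        r1 = nbs(t2, t1, design="paired", threshold=3.0, n_perm=200, seed=9)
        r2 = nbs(t2, t1, design="paired", threshold=3.0, n_perm=200, seed=9)
        assert np.array_equal(r1.null_max_extent, r2.null_max_extent)
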