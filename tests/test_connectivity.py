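import itertools

import numpy as np
import pytest

from oakphylo.connectivity import (
    area_by_elevation_bin,
    classify_by_breaks,
    combine_habitat,
    eca,
    extract_patches,
    jenks_breaks,
    least_cost_distances,
    rescale_suitability,
    resistance_from_habitat,
    select_uncorrelated_variables,
    thin_occurrences,
    tri,
)
from oakphylo.raster import Raster, read_ascii_grid, write_ascii_grid


class TestRasterIO:
    def test_ascii_roundtrip(self, tmp_path):
        r = Raster(np.arange(12, dtype=float).reshape(3, 4), cell_size=0.5,
                   x_origin=10.0, y_origin=20.0, nodata=-1.0)
        p = tmp_path / "r.asc"
        write_ascii_grid(r, str(p))
        back = read_ascii_grid(str(p))
        np.testing.assert_allclose(back.values, r.values)
        assert back.cell_size == 0.5
        assert back.nodata == -1.0


class TestThinOccurrences:
    def test_close_pair_one_kept(self):
        pts = np.array([[0.0, 0.0], [0.03, 0.0]])  # ~3.3 km apart
        assert thin_occurrences(pts, 10.0).shape[0] == 1

    def test_far_points_identity(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])  # ~111 km apart
        assert thin_occurrences(pts, 10.0).shape[0] == 3

    def test_cluster_plus_isolated(self):
        cluster = [[0.0, 0.0], [0.01, 0.01], [0.02, 0.0], [0.0, 0.02], [0.01, 0.0]]
        isolated = [[3.0, 3.0]]
        kept = thin_occurrences(np.array(cluster + isolated), 10.0)
        assert kept.shape[0] == 2


class TestSelectUncorrelated:
    def test_duplicate_dropped(self):
        rng = np.random.default_rng(0)
        base = Raster(rng.random((10, 10)))
        rasters = {"general": base, "specific": base.like(base.values * 2 + 1)}
        kept = select_uncorrelated_variables(rasters, ["general", "specific"])
        assert kept == ["general"]

    def test_orthogonal_checkerboards_kept(self):
        a = np.indices((8, 8)).sum(axis=0) % 2
        b = np.indices((8, 8))[0] % 2
        rasters = {"a": Raster(a.astype(float)), "b": Raster(b.astype(float))}
        kept = select_uncorrelated_variables(rasters, ["a", "b"])
        assert kept == ["a", "b"]

    def test_one_correlated_pair_of_three(self):
        rng = np.random.default_rng(1)
        x = rng.random((12, 12))
        rasters = {
            "v1": Raster(x),
            "v2": Raster(x + rng.normal(0, 0.01, x.shape)),  # ~ v1
            "v3": Raster(rng.random((12, 12))),
        }
        kept = select_uncorrelated_variables(rasters, ["v1", "v2", "v3"])
        assert kept == ["v1", "v3"]

    def test_misaligned_error(self):
        with pytest.raises(ValueError):
            select_uncorrelated_variables(
                {"a": Raster(np.ones((3, 3))), "b": Raster(np.ones((4, 4)))},
                ["a", "b"],
            )


class TestTri:
    def test_flat_dem_zero(self):
        out = tri(Raster(np.full((5, 5), 42.0)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_center_peak(self):
        z = np.full((3, 3), 9.0)
        z[1, 1] = 10.0
        out = tri(Raster(z))
        assert out.values[1, 1] == pytest.approx(np.sqrt(8.0))

    def test_nodata_neighbor_excluded(self):
        z = np.full((3, 3), 9.0)
        z[1, 1] = 10.0
        z[0, 0] = -9999.0
        out = tri(Raster(z))
        assert out.values[1, 1] == pytest.approx(np.sqrt(7.0))
        assert out.values[0, 0] == -9999.0

    def test_all_nodata_error(self):
        with pytest.raises(ValueError):
            tri(Raster(np.full((3, 3), -9999.0)))


class TestJenks:
    def test_two_cluster_break(self):
        bounds = jenks_breaks(np.array([1, 2, 100, 101]), k=2)
        assert bounds[0] == 1
        assert 2 <= bounds[1] < 100
        assert bounds[2] == 101

    def test_k1_single_class(self):
        bounds = jenks_breaks(np.array([3.0, 5.0, 9.0]), k=1)
        assert len(bounds) == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(60)
        b1 = jenks_breaks(vals, k=4)
        b2 = jenks_breaks(vals[rng.permutation(60)], k=4)
        np.testing.assert_allclose(b1, b2)

    def test_exhaustive_partition_search_oracle(self):
        """DP solution equals brute-force search over ordered partitions."""
        rng = np.random.default_rng(5)
        vals = np.sort(rng.random(12) * 10)
        k = 3

        def ssd(chunk):
            return float(np.sum((chunk - chunk.mean()) ** 2))

        best = np.inf
        for cut in itertools.combinations(range(1, 12), k - 1):
            parts = np.split(vals, list(cut))
            cost = sum(ssd(p) for p in parts)
            best = min(best, cost)
        bounds = jenks_breaks(vals, k=k)
        classes = np.digitize(vals, bounds[1:-1], right=True)
        got = sum(ssd(vals[classes == c]) for c in np.unique(classes))
        assert got == pytest.approx(best, abs=1e-9)

    def test_too_few_distinct_values_warns(self):
        with pytest.warns(UserWarning, match="reducing k"):
            jenks_breaks(np.array([1.0, 1.0, 2.0]), k=5)


class TestRescale:
    def test_boundary_value(self):
        r = rescale_suitability(Raster(np.array([[0.4]])), threshold=0.4)
        assert r.values[0, 0] == 100.0

    def test_zero(self):
        r = rescale_suitability(Raster(np.array([[1e-12]])), threshold=0.4)
        assert r.values[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_hand_value(self):
        r = rescale_suitability(Raster(np.array([[0.1]])), threshold=0.4)
        assert r.values[0, 0] == pytest.approx(25.0)

    def test_monotone(self):
        vals = np.linspace(0, 1, 50)[None, :]
        out = rescale_suitability(Raster(vals), threshold=0.3).values[0]
        assert (np.diff(out) >= -1e-9).all()

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            rescale_suitability(Raster(np.ones((2, 2))), threshold=0.0)


class TestCombine:
    def test_equal_layers_identity(self):
        a = Raster(np.random.default_rng(0).random((4, 4)) * 100)
        out = combine_habitat(a, a.like(a.values.copy()))
        np.testing.assert_allclose(out.values, a.values)

    def test_mean(self):
        a = Raster(np.full((2, 2), 100.0))
        b = Raster(np.zeros((2, 2)))
        assert combine_habitat(a, b).values[0, 0] == 50.0

    def test_degenerate_weights(self):
        a = Raster(np.full((2, 2), 77.0))
        b = Raster(np.zeros((2, 2)))
        np.testing.assert_allclose(combine_habitat(a, b, (1.0, 0.0)).values, 77.0)


class TestPatches:
    def test_uniform_raster_single_patch(self):
        p = extract_patches(Raster(np.full((5, 5), 100.0)))
        assert p.n_patches == 1
        assert p.areas[0] == 25.0

    def test_subthreshold_corridor_two_patches(self):
        z = np.full((3, 7), 100.0)
        z[:, 3] = 10.0
        p = extract_patches(Raster(z), min_mean_value=50)
        assert p.n_patches == 2

    def test_diagonal_cells_merge(self):
        z = np.zeros((4, 4))
        z[0, 0] = z[1, 1] = 100.0
        p = extract_patches(Raster(z), min_mean_value=50)
        assert p.n_patches == 1

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="no habitat"):
            p = extract_patches(Raster(np.zeros((3, 3))), min_mean_value=50)
        assert p.n_patches == 0


def grid_graph_brute_force(resistance: Raster, src_rc, dst_rc):
    """Minimum-cost path by exhaustive enumeration of simple paths."""
    import networkx as nx

    z = resistance.masked()
    g = nx.Graph()
    rows, cols = z.shape
    for r in range(rows):
        for c in range(cols):
            if not np.isfinite(z[r, c]):
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and np.isfinite(z[r2, c2]):
                    mult = np.sqrt(2) if dr and dc else 1.0
                    w = 0.5 * (z[r, c] + z[r2, c2]) * mult * resistance.cell_size
                    g.add_edge((r, c), (r2, c2), weight=w)
    best = np.inf
    for path in nx.all_simple_paths(g, src_rc, dst_rc):
        cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        best = min(best, cost)
    return best


class TestLeastCost:
    def _patchset(self, habitat, threshold=50.0):
        return extract_patches(habitat, min_mean_value=threshold)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(60, 100, (6, 6))
        z[:, 3] = 1.0  # corridor below threshold separates two patches
        hab = Raster(z)
        patches = self._patchset(hab)
        d = least_cost_distances(resistance_from_habitat(hab), patches)
        assert d.shape == (patches.n_patches, patches.n_patches)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d[~np.eye(d.shape[0], dtype=bool)] > 0).all()

    def test_uniform_resistance_proportionality(self):
        # single-cell patches at two corners of a uniform-resistance grid
        z = np.zeros((10, 10))
        z[0, 0] = z[9, 9] = 100.0
        hab = Raster(z + 50.0 * (z == 0))  # patches 100, matrix 50
        patches = extract_patches(hab, min_mean_value=90)
        res = Raster(np.full((10, 10), 4.0))
        d = least_cost_distances(res, patches)
        # geometric shortest path: 9 diagonal moves
        assert d[0, 1] == pytest.approx(9 * np.sqrt(2) * 4.0)

    def test_dijkstra_equals_path_enumeration(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            z = rng.uniform(1, 10, (4, 4))
            res = Raster(z)
            hab = np.zeros((4, 4))
            hab[0, 0] = hab[3, 3] = 100.0
            patches = extract_patches(Raster(hab), min_mean_value=90)
            d = least_cost_distances(res, patches)
            brute = grid_graph_brute_force(res, (0, 0), (3, 3))
            assert d[0, 1] == pytest.approx(brute)

    def test_cost_threshold_unreachable(self):
        z = np.zeros((3, 5))
        z[:, 0] = z[:, 4] = 100.0
        hab = Raster(z)
        patches = extract_patches(hab, min_mean_value=90)
        d = least_cost_distances(resistance_from_habitat(hab), patches, cost_threshold=1.0)
        assert np.isinf(d[0, 1])


class TestEca:
    def _single(self, areas, dists=None):
        class P:
            pass

        p = P()
        p.areas = np.asarray(areas, dtype=float)
        if dists is None:
            dists = np.zeros((len(areas), len(areas)))
        return p, np.asarray(dists, dtype=float)

    def test_single_patch_identity(self):
        p, d = self._single([7.0])
        assert eca(p, d).eca == pytest.approx(7.0)

    def test_two_unreachable(self):
        p, d = self._single([1.0, 1.0], [[0, np.inf], [np.inf, 0]])
        assert eca(p, d).eca == pytest.approx(np.sqrt(2.0))

    def test_two_patch_hand_formula(self):
        # p* = 0.5 at distance d_ref
        p, d = self._single([2.0, 3.0], [[0, 1.0], [1.0, 0]])
        res = eca(p, d, p_ref=0.5, d_ref=1.0)
        assert res.eca == pytest.approx(np.sqrt(4 + 9 + 2 * 2 * 3 * 0.5))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(2, 6)
            areas = rng.uniform(0.5, 5, n)
            d = rng.uniform(0.1, 10, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            p, dm = self._single(areas, d)
            val = eca(p, dm).eca
            assert np.sqrt(np.sum(areas**2)) - 1e-9 <= val <= areas.sum() + 1e-9

    def test_monotone_in_links(self):
        p, d = self._single([1.0, 2.0, 3.0])
        far = np.full((3, 3), np.inf)
        np.fill_diagonal(far, 0)
        base = eca(p, far).eca
        d1 = far.copy()
        d1[0, 1] = d1[1, 0] = 2.0
        with_link = eca(p, d1).eca
        d2 = d1.copy()
        d2[1, 2] = d2[2, 1] = 2.0
        with_two = eca(p, d2).eca
        assert base < with_link < with_two

    def test_decreasing_distance_increases_eca(self):
        p, _ = self._single([1.0, 1.0])
        near = eca(p, np.array([[0, 1.0], [1.0, 0]])).eca
        nearer = eca(p, np.array([[0, 0.5], [0.5, 0]])).eca
        assert nearer > near

    def test_max_product_path_beats_direct(self):
        # chain where the indirect route through the middle patch is better
        p, _ = self._single([1.0, 1.0, 1.0])
        d = np.array([[0, 1.0, 10.0], [1.0, 0, 1.0], [10.0, 1.0, 0]])
        routed = eca(p, d)
        direct = eca(p, d, direct_only=True)
        assert routed.probabilities[0, 2] == pytest.approx(0.25)
        assert direct.probabilities[0, 2] == pytest.approx(0.5**10)
        assert routed.eca > direct.eca

    def test_bad_dref(self):
        p, d = self._single([1.0])
        with pytest.raises(ValueError):
            eca(p, d, d_ref=0.0)


class TestAreaByElevation:
    def test_uniform_single_bin(self):
        dem = Raster(np.full((4, 4), 250.0))
        t = area_by_elevation_bin(dem)
        nz = t[t["area_km2"] > 0]
        assert len(nz) == 1
        assert nz["area_km2"].iloc[0] == 16.0

    def test_two_level_counts(self):
        z = np.full((4, 4), 150.0)
        z[:2] = 450.0
        t = area_by_elevation_bin(Raster(z), bin_width=100.0)
        areas = dict(zip(t["bin_low"], t["area_km2"]))
        assert areas[100.0] == 8.0
        assert areas[400.0] == 8.0

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(0)
        dem = Raster(rng.uniform(0, 3000, (20, 20)), cell_size=0.5)
        t = area_by_elevation_bin(dem)
        assert t["area_km2"].sum() == pytest.approx(400 * 0.25)


class TestClassify:
    def test_classes_cover_range(self):
        rng = np.random.default_rng(0)
        r = Raster(rng.random((10, 10)) * 100)
        breaks = jenks_breaks(r.values.ravel(), k=5)
        cls = classify_by_breaks(r, breaks)
        assert cls.values.min() >= 1
        assert cls.values.max() <= 5
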