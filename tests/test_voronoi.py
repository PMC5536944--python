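"""Tessellation geometry, local densities and nanodomain segmentation.

The independent geometry oracle clips each cell as an intersection of
bisector half-planes with the region polygon (shapely), with no reference
to the production code path.
"""

import numpy as np
import pytest
from shapely.geometry import Polygon

from nanotess import (DensityParams, GeometryError, build_voronoi,
                      local_density, nanodomain_stats, segment_clusters)


def _halfplane(points, i, j, span):
    """Closed half-plane {x : |x - p_i| <= |x - p_j|} as a big polygon."""
    mid = (points[i] + points[j]) / 2
    normal = points[i] - points[j]
    normal = normal / np.linalg.norm(normal)
    tangent = np.array([-normal[1], normal[0]])
    return Polygon([mid - tangent * span, mid + tangent * span,
                    mid + tangent * span + normal * span,
                    mid - tangent * span + normal * span])


def halfplane_oracle(points, region: Polygon):
    """Brute-force Voronoï cells: region ∩ (bisector half-planes).

    Adjacency of (i, j) is decided by clipping the (i, j) bisector line by
    the region and all of i's other half-planes — a transversal (hence
    numerically robust) construction.  Returns (areas, adjacency sets).
    """
    from shapely.geometry import LineString

    points = np.asarray(points, float)
    n = len(points)
    span = max(np.ptp(points), 1.0) * 100
    cells = []
    for i in range(n):
        cell = region
        for j in range(n):
            if i != j:
                cell = cell.intersection(_halfplane(points, i, j, span))
                if cell.is_empty:
                    break
        cells.append(cell)
    areas = np.array([c.area for c in cells])
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            mid = (points[i] + points[j]) / 2
            normal = points[i] - points[j]
            normal = normal / np.linalg.norm(normal)
            tangent = np.array([-normal[1], normal[0]])
            ridge = LineString([mid - tangent * span,
                                mid + tangent * span]).intersection(region)
            for k in range(n):
                if k in (i, j) or ridge.is_empty:
                    continue
                ridge = ridge.intersection(_halfplane(points, i, k, span))
            if not ridge.is_empty and ridge.length > 1e-9:
                adj[i].add(j)
                adj[j].add(i)
    return areas, adj


def oracle_delta1(areas, adj):
    out = np.empty(len(areas))
    for i in range(len(areas)):
        group = {i} | adj[i]
        out[i] = len(group) / sum(areas[g] for g in group)
    return out


class TestBuildVoronoi:
    def test_four_point_square_symmetry(self):
        region = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])
        pts = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
        vmap = build_voronoi(pts, region=region)
        np.testing.assert_allclose(vmap.areas, 1.0, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_clipped_cells_partition_region(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, size=(40, 2))
        vmap = build_voronoi(pts)  # region = convex hull
        assert abs(vmap.areas.sum() - vmap.region_area) \
            <= 1e-6 * vmap.region_area

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_halfplane_oracle(self, seed):
        rng = np.random.default_rng(seed)
        region = Polygon([(0, 0), (1000, 0), (1000, 800), (0, 800)])
        pts = rng.uniform((0, 0), (1000, 800), size=(30, 2))
        vmap = build_voronoi(pts, region=region)
        areas, adj = halfplane_oracle(pts, region)
        np.testing.assert_allclose(vmap.areas, areas, rtol=1e-6)
        for i in range(len(pts)):
            assert set(vmap.neighbors[i].tolist()) == adj[i], f"cell {i}"
        d_imp, dn_imp = local_density(vmap)
        np.testing.assert_allclose(d_imp, oracle_delta1(areas, adj), rtol=1e-6)
        assert dn_imp == pytest.approx(len(pts) / region.area, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            build_voronoi(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(GeometryError):
            build_voronoi(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))

    def test_duplicate_points_perturbed_not_fatal(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0],
                        [100.0, 100.0], [100.0, 100.0]])
        vmap = build_voronoi(pts)
        assert vmap.n_points == 5
        assert np.all(vmap.areas >= 0)


class TestLocalDensity:
    def test_square_lattice_interior_density(self):
        """On a square lattice of spacing a every interior cell is an a×a
        square, so δ¹ᵢ = (1+k)/((1+k)·a²) = 1/a² whatever the resolved
        neighbour count k."""
        a = 10.0
        g = np.arange(7) * a
        pts = np.array([(x, y) for x in g for y in g], float)
        region = Polygon([(-a / 2, -a / 2), (6 * a + a / 2, -a / 2),
                          (6 * a + a / 2, 6 * a + a / 2), (-a / 2, 6 * a + a / 2)])
        vmap = build_voronoi(pts, region=region)
        delta, delta_n = local_density(vmap)
        centre = np.flatnonzero((pts[:, 0] == 3 * a) & (pts[:, 1] == 3 * a))[0]
        assert delta[centre] == pytest.approx(1 / a ** 2, rel=1e-9)
        assert delta_n == pytest.approx(1 / a ** 2, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 500, size=(60, 2))
        s = 3.0
        v1 = build_voronoi(pts)
        v2 = build_voronoi(pts * s)
        np.testing.assert_allclose(v2.areas, v1.areas * s ** 2, rtol=1e-9)
        d1, dn1 = local_density(v1)
        d2, dn2 = local_density(v2)
        np.testing.assert_allclose(d2, d1 / s ** 2, rtol=1e-9)
        assert dn2 == pytest.approx(dn1 / s ** 2, rel=1e-9)
        c1 = segment_clusters(v1, (d1, dn1))
        c2 = segment_clusters(v2, (d2, dn2))
        assert [m.tolist() for m in c1.members] == [m.tolist() for m in c2.members]


def _disk_instance(n_in=20, n_bg=500, disk_r=50.0, field=10_000.0, seed=0):
    rng = np.random.default_rng(seed)
    centre = np.array([field / 2, field / 2])
    rr = disk_r * np.sqrt(rng.uniform(size=n_in))
    th = rng.uniform(0, 2 * np.pi, size=n_in)
    inside = centre + np.c_[rr * np.cos(th), rr * np.sin(th)]
    bg = rng.uniform(0, field, size=(n_bg, 2))
    return np.vstack([inside, bg]), np.arange(n_in)


class TestSegmentation:
    def test_single_dense_disk_found(self):
        """20 molecules in one 50-nm disk over a sparse 10×10 µm field give
        exactly one cluster holding nearly all disk members."""
        pts, disk_ids = _disk_instance(seed=3)
        vmap = build_voronoi(pts)
        clusters = segment_clusters(vmap, local_density(vmap))
        assert len(clusters) == 1
        members = set(clusters.members[0].tolist())
        assert len(members & set(disk_ids.tolist())) >= 18

    def test_min_locs_filter(self):
        """A candidate component of 4 molecules is discarded at min_locs=5
        but kept at min_locs=4.

        A uniform lattice keeps every background δ¹ᵢ near δ_N so the only
        candidates are the 4 tightly packed extra molecules.
        """
        a = 100.0
        g = np.arange(15) * a
        lattice = np.array([(x, y) for x in g for y in g], float)
        clump = np.array([[745.0, 745.0], [755.0, 745.0],
                          [745.0, 755.0], [755.0, 755.0]])
        pts = np.vstack([lattice, clump])
        region = Polygon([(-a / 2, -a / 2), (14 * a + a / 2, -a / 2),
                          (14 * a + a / 2, 14 * a + a / 2),
                          (-a / 2, 14 * a + a / 2)])
        vmap = build_voronoi(pts, region=region)
        dens = local_density(vmap)
        assert len(segment_clusters(vmap, dens, DensityParams())) == 0
        kept = segment_clusters(vmap, dens, DensityParams(min_locs=4))
        assert len(kept) == 1 and kept.table["n_locs"].iloc[0] == 4

    def test_threshold_monotonicity(self):
        pts, _ = _disk_instance(n_in=30, n_bg=300, seed=6)
        vmap = build_voronoi(pts)
        dens = local_density(vmap)
        counts = [segment_clusters(vmap, dens,
                                   DensityParams(threshold_factor=tf,
                                                 min_locs=1, min_area=1e-6)
                                   ).n_clustered_molecules
                  for tf in (1.0, 1.5, 2.0, 3.0, 5.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_uniform_field_false_positive_rate(self):
        """Pure Poisson fields: mean fraction of molecules in clusters stays
        below 5%."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            pts = rng.uniform(0, 2000, size=(400, 2))
            vmap = build_voronoi(pts)
            cl = segment_clusters(vmap, local_density(vmap))
            fracs.append(cl.n_clustered_molecules / len(pts))
        assert np.mean(fracs) < 0.05

    def test_cluster_invariants(self):
        pts, _ = _disk_instance(n_in=25, n_bg=200, seed=8)
        vmap = build_voronoi(pts)
        cl = segment_clusters(vmap, local_density(vmap))
        ids = np.concatenate(cl.members) if cl.members else np.empty(0)
        assert len(np.unique(ids)) == len(ids)  # disjoint clusters
        for _, row in cl.table.iterrows():
            assert row["n_locs"] >= 5 and row["area_nm2"] >= 32.0
            assert row["diameter_nm"] == pytest.approx(
                2 * np.sqrt(row["area_nm2"] / np.pi))


class TestNanodomainStats:
    def test_equivalent_diameter_formula(self):
        pts, _ = _disk_instance(seed=3)
        vmap = build_voronoi(pts)
        cl = segment_clusters(vmap, local_density(vmap))
        st = nanodomain_stats(cl, vmap)
        a = cl.table["area_nm2"].iloc[0]
        assert st.mean_diameter_nm == pytest.approx(2 * np.sqrt(a / np.pi))
        assert 0 <= st.pct_surface <= 100 and 0 <= st.pct_molecules <= 100

    def test_empty_clusters_warn_and_zero(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 3000, size=(40, 2))
        vmap = build_voronoi(pts)
        cl = segment_clusters(vmap, local_density(vmap),
                              DensityParams(threshold_factor=50.0))
        with pytest.warns(UserWarning):
            st = nanodomain_stats(cl, vmap)
        assert st.pct_surface == 0 and st.pct_molecules == 0 \
            and st.density_per_um2 == 0
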