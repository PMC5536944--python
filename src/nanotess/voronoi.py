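"""Voronoï-tessellation segmentation of membrane nanodomains.

Each merged molecule position seeds a Voronoï cell; the cell area is
inversely proportional to the local molecular density.  The first-rank
local density around molecule *i* is

    δ¹ᵢ = (1 + |N(i)|) / (Aᵢ + Σ_{j∈N(i)} Aⱼ)

where N(i) are the cells sharing an edge with cell *i* and A are the cell
areas clipped to the analysis region.  Nanodomains are the connected
components of molecules whose δ¹ᵢ exceeds a multiple (default 2) of the
region-average density δ_N = N / region area, kept if they contain at
least 5 molecules and cover at least 32 nm².

All coordinates and areas are in nm / nm²; reported nanodomain densities
are per µm².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Voronoi
from shapely.geometry import LineString, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "VoronoiMap",
    "DensityParams",
    "ClusterSet",
    "NanodomainStats",
    "build_voronoi",
    "local_density",
    "segment_clusters",
    "nanodomain_stats",
]

_ZERO_AREA_TOL = 1e-9  # nm², cells below this are flagged degenerate
_RIDGE_LEN_TOL = 1e-9  # nm, shorter shared edges do not count as adjacency


class GeometryError(ValueError):
    """Raised for degenerate point sets (<3 points, collinear, ...)."""


@dataclass
class VoronoiMap:
    """Clipped Voronoï tessellation of molecule positions.

    ``areas`` are the cell areas after clipping to ``region``;
    ``neighbors[i]`` lists first-rank neighbours (cells sharing an edge of
    positive length inside the region); ``bounded[i]`` is False for cells
    that were unbounded before clipping.
    """

    points: np.ndarray  # (n, 2) nm
    areas: np.ndarray  # (n,) nm²
    neighbors: list  # list of int arrays
    bounded: np.ndarray  # (n,) bool
    region: Polygon
    excluded: np.ndarray  # ids of degenerate (zero-area) cells

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def region_area(self) -> float:
        return float(self.region.area)


@dataclass(frozen=True)
class DensityParams:
    """Nanodomain segmentation parameters (defaults follow the method)."""

    threshold_factor: float = 2.0  # candidate if δ¹ᵢ > factor · δ_N
    min_area: float = 32.0  # nm²
    min_locs: int = 5
    rank: int = 1

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0 or self.min_area <= 0 \
                or self.min_locs <= 0 or self.rank <= 0:
            raise ValueError("all segmentation parameters must be positive")


def _dedupe_points(points: np.ndarray) -> np.ndarray:
    """Perturb exact duplicates by a deterministic 1e-3 nm jitter."""
    pts = points.astype(float).copy()
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True,
                                   return_counts=True)
    if counts.max() <= 1:
        return pts
    n_dup = 0
    seen: dict[int, int] = {}
    for i, g in enumerate(inverse):
        k = seen.get(int(g), 0)
        seen[int(g)] = k + 1
        if k:  # golden-angle spiral keyed on the row index, offset 1e-3 nm
            ang = 2.399963229728653 * i
            pts[i, 0] += 1e-3 * k * np.cos(ang)
            pts[i, 1] += 1e-3 * k * np.sin(ang)
            n_dup += 1
    logger.warning("perturbed %d duplicate coordinates by ~1e-3 nm", n_dup)
    return pts


def _finite_polygons(vor: Voronoi, radius: float):
    """Reconstruct finite polygons for all cells of a 2-D Voronoi diagram.

    Unbounded regions are closed by extending their infinite ridges to
    ``radius`` (must exceed any distance relevant after clipping).
    Returns (list of vertex arrays, bounded flags).
    """
    center = vor.points.mean(axis=0)
    # map point -> its ridges
    ridges: dict[int, list] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        ridges.setdefault(p1, []).append((p2, v1, v2))
        ridges.setdefault(p2, []).append((p1, v1, v2))

    polys = []
    bounded = np.ones(len(vor.points), bool)
    for p, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if -1 not in region:
            polys.append(vor.vertices[region])
            continue
        bounded[p] = False
        verts = [vor.vertices[v] for v in region if v != -1]
        for p2, v1, v2 in ridges.get(p, []):
            if v1 != -1 and v2 != -1:
                continue
            v = v2 if v1 == -1 else v1
            tangent = vor.points[p2] - vor.points[p]
            tangent = tangent / np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = (vor.points[p] + vor.points[p2]) / 2
            if np.dot(midpoint - center, normal) < 0:
                normal = -normal
            verts.append(vor.vertices[v] + normal * radius)
        verts = np.asarray(verts)
        # order by angle around the seed to get a simple polygon
        ang = np.arctan2(verts[:, 1] - vor.points[p, 1],
                         verts[:, 0] - vor.points[p, 0])
        polys.append(verts[np.argsort(ang)])
    return polys, bounded


def build_voronoi(molecules, region=None) -> VoronoiMap:
    """Tessellate molecule positions and clip the cells to a region.

    ``molecules`` may be a MoleculeSet, a DataFrame with x/y columns or an
    (n, 2) array (nm).  ``region`` is a shapely Polygon or an (m, 2) vertex
    array; by default the convex hull of the positions.  The clipped cell
    areas partition the region exactly.
    """
    if hasattr(molecules, "xy"):
        points = np.asarray(molecules.xy, float)
    elif isinstance(molecules, pd.DataFrame):
        points = molecules[["x", "y"]].to_numpy(float)
    else:
        points = np.asarray(molecules, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise GeometryError("expected an (n, 2) array of positions")
    if len(points) < 3:
        raise GeometryError("need at least 3 molecules to tessellate")
    if not np.all(np.isfinite(points)):
        raise GeometryError("positions must be finite")
    points = _dedupe_points(points)
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * (1 + np.abs(centered).max())) < 2:
        raise GeometryError("all points are collinear")

    if region is None:
        hull = ConvexHull(points)
        region_poly = Polygon(points[hull.vertices])
    elif isinstance(region, Polygon):
        region_poly = region
    else:
        region_poly = Polygon(np.asarray(region, float))
    if not region_poly.is_valid or region_poly.area <= 0:
        raise GeometryError("region polygon is invalid or empty")

    span = float(np.ptp(points, axis=0).max())
    bounds = region_poly.bounds
    radius = 10.0 * (span + (bounds[2] - bounds[0]) + (bounds[3] - bounds[1]) + 1.0)

    vor = Voronoi(points)
    polys, bounded = _finite_polygons(vor, radius)

    # areas: fast shoelace for cells fully inside the region, shapely clip else
    inside = shapely.contains_xy  # vectorized point-in-polygon
    areas = np.empty(len(points))
    cell_polys: list[Polygon | None] = [None] * len(points)
    for i, verts in enumerate(polys):
        if len(verts) < 3:
            areas[i] = 0.0
            continue
        if bounded[i] and np.all(inside(region_poly, verts[:, 0], verts[:, 1])):
            x, y = verts[:, 0], verts[:, 1]
            areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        else:
            poly = Polygon(verts)
            if not poly.is_valid:
                poly = poly.buffer(0)
            clipped = poly.intersection(region_poly)
            areas[i] = float(clipped.area)
            cell_polys[i] = clipped

    excluded = np.flatnonzero(areas <= _ZERO_AREA_TOL)
    if len(excluded):
        logger.warning("%d zero-area cells flagged and excluded", len(excluded))

    # adjacency: Voronoi ridges with positive length inside the region
    neigh: list[set] = [set() for _ in range(len(points))]
    verts_all = vor.vertices
    if len(verts_all):
        v_inside = inside(region_poly, verts_all[:, 0], verts_all[:, 1])
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 != -1 and v2 != -1:
            a, b = verts_all[v1], verts_all[v2]
            if np.hypot(*(a - b)) <= _RIDGE_LEN_TOL:
                continue  # degenerate (cocircular) ridge
            if v_inside[v1] and v_inside[v2]:
                keep = True
            else:
                keep = LineString([a, b]).intersection(region_poly).length \
                    > _RIDGE_LEN_TOL
        else:
            v = v2 if v1 == -1 else v1
            t = points[p2] - points[p1]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = (points[p1] + points[p2]) / 2
            if np.dot(midpoint - points.mean(axis=0), normal) < 0:
                normal = -normal
            far = verts_all[v] + normal * radius
            keep = LineString([verts_all[v], far]).intersection(region_poly) \
                .length > _RIDGE_LEN_TOL
        if keep:
            neigh[p1].add(p2)
            neigh[p2].add(p1)
    neighbors = [np.asarray(sorted(s), int) for s in neigh]

    total = areas.sum()
    if abs(total - region_poly.area) > 1e-6 * region_poly.area:
        logger.warning("cell areas sum to %.6g but region area is %.6g",
                       total, region_poly.area)
    return VoronoiMap(points=points, areas=areas, neighbors=neighbors,
                      bounded=bounded, region=region_poly, excluded=excluded)


def local_density(vmap: VoronoiMap, rank: int = 1):
    """First-rank local densities δ¹ᵢ (nm⁻²) and the average density δ_N.

    δ¹ᵢ counts the cell and its neighbours within ``rank`` adjacency steps
    and divides by their summed areas.  Degenerate zero-area cells get NaN
    and do not contribute to their neighbours' sums.  δ_N is the molecule
    count over the region area.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n = vmap.n_points
    bad = set(vmap.excluded.tolist())
    delta = np.full(n, np.nan)
    for i in range(n):
        if i in bad:
            continue
        group = {i}
        frontier = {i}
        for _ in range(rank):
            nxt = set()
            for j in frontier:
                nxt.update(int(k) for k in vmap.neighbors[j])
            frontier = nxt - group
            group |= frontier
        group -= bad
        area = float(np.sum(vmap.areas[sorted(group)]))
        if area > 0:
            delta[i] = len(group) / area
    delta_n = (n - len(bad)) / vmap.region_area
    return delta, delta_n


@dataclass
class ClusterSet:
    """Segmented nanodomains.

    ``table`` columns: n_locs, area_nm2, diameter_nm, cx, cy.  ``members``
    holds the molecule ids of each cluster; ``molecule_cluster`` maps every
    molecule to its cluster id (-1 outside nanodomains).
    """

    table: pd.DataFrame
    members: list
    molecule_cluster: np.ndarray
    params: DensityParams

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_clustered_molecules(self) -> int:
        return int(self.table["n_locs"].sum())


def segment_clusters(vmap: VoronoiMap, densities=None,
                     params: DensityParams = DensityParams()) -> ClusterSet:
    """Segment nanodomains by density thresholding the tessellation.

    Candidate molecules satisfy δ¹ᵢ > threshold_factor · δ_N; clusters are
    connected components of the adjacency graph restricted to candidates,
    kept when they have ≥ min_locs members and ≥ min_area nm² of summed
    cell area.  Cluster area is the sum of member cell areas and the
    equivalent diameter is 2·√(area/π).
    """
    if densities is None:
        densities = local_density(vmap, rank=params.rank)
    delta, delta_n = densities
    delta = np.asarray(delta, float)
    with np.errstate(invalid="ignore"):
        cand = delta > params.threshold_factor * delta_n

    # union-find over adjacency restricted to candidates
    parent = np.arange(vmap.n_points)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in np.flatnonzero(cand):
        for j in vmap.neighbors[i]:
            if cand[j]:
                ri, rj = find(int(i)), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in np.flatnonzero(cand):
        groups.setdefault(find(int(i)), []).append(int(i))

    rows = []
    members = []
    mol_cluster = np.full(vmap.n_points, -1, int)
    for root in sorted(groups):
        ids = np.asarray(groups[root], int)
        area = float(np.sum(vmap.areas[ids]))
        if len(ids) < params.min_locs or area < params.min_area:
            continue
        cid = len(rows)
        mol_cluster[ids] = cid
        members.append(ids)
        cx, cy = vmap.points[ids].mean(axis=0)
        rows.append({"n_locs": len(ids), "area_nm2": area,
                     "diameter_nm": 2.0 * np.sqrt(area / np.pi),
                     "cx": float(cx), "cy": float(cy)})
    table = pd.DataFrame(rows, columns=["n_locs", "area_nm2", "diameter_nm",
                                        "cx", "cy"])
    return ClusterSet(table=table, members=members,
                      molecule_cluster=mol_cluster, params=params)


@dataclass
class NanodomainStats:
    """Whole-region nanodomain summary (the standard figure panels)."""

    n_clusters: int
    mean_diameter_nm: float
    fit_mode_diameter_nm: float  # mode of a Gaussian fitted to the histogram
    pct_surface: float  # % of the region area inside nanodomains
    pct_molecules: float  # % of molecules inside nanodomains
    density_per_um2: float  # nanodomains per µm²


def _gaussian_mode(values: np.ndarray) -> float:
    """Mode of a Gaussian fitted to the histogram of ``values``.

    Least-squares fit of a·exp(−(x−µ)²/2s²) to the histogram counts; falls
    back to the sample mean when the sample is small or the fit fails.
    """
    values = np.asarray(values, float)
    if len(values) < 10 or np.ptp(values) == 0:
        return float(np.mean(values))
    from scipy.optimize import curve_fit

    nbins = max(10, int(round(np.sqrt(len(values)))))
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, s):
        return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                gauss, centers, counts,
                p0=(counts.max(), float(np.median(values)), float(np.std(values)) or 1.0),
                maxfev=5000)
        mu = float(popt[1])
        if edges[0] - np.ptp(values) <= mu <= edges[-1] + np.ptp(values):
            return mu
    except Exception:  # singular fits on ragged histograms
        pass
    return float(np.mean(values))


def nanodomain_stats(clusters: ClusterSet, vmap: VoronoiMap) -> NanodomainStats:
    """Summary statistics of the segmented nanodomains.

    Reports the arithmetic-mean and Gaussian-fit-mode diameter, the percent
    of the region surface covered, the percent of molecules inside
    nanodomains and the nanodomain density in µm⁻².  An empty cluster set
    yields zeros with a warning.
    """
    area_um2 = vmap.region_area * 1e-6
    if len(clusters) == 0:
        warnings.warn("no clusters found; statistics are all zero")
        return NanodomainStats(0, 0.0, 0.0, 0.0, 0.0, 0.0)
    d = clusters.table["diameter_nm"].to_numpy(float)
    total_cluster_area = float(clusters.table["area_nm2"].sum())
    n_valid = vmap.n_points - len(vmap.excluded)
    return NanodomainStats(
        n_clusters=len(clusters),
        mean_diameter_nm=float(np.mean(d)),
        fit_mode_diameter_nm=_gaussian_mode(d),
        pct_surface=100.0 * total_cluster_area / vmap.region_area,
        pct_molecules=100.0 * clusters.n_clustered_molecules / n_valid,
        density_per_um2=len(clusters) / area_um2,
    )
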