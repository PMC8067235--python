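"""Strain-field reduction and critical-region statistics.

The damage surrogate is the equivalent (von Mises effective) strain

    eps_eq = 1/(1 + nu') * sqrt( 1/2 [ (e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2 ] )

of the nodal log-strain tensor with effective Poisson ratio nu' = 0.5
(incompressible tissue; configurable).  Tissue locations whose peak
equivalent strain over the simulated period exceeds the critical threshold
0.05 form the "critical region"; its size is measured as the volume of an
alpha shape over the centroids of the affected elements, with the alpha
radius chosen as the smaller of (a) the radius of the smallest sphere
enclosing the critical points and (b) the maximum element characteristic
length of the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Point

from . import geometry as geo

__all__ = [
    "ROISpec",
    "CriticalRegion",
    "equivalent_strain",
    "roi_strain_timeseries",
    "peak_strain_field",
    "critical_points",
    "smallest_enclosing_sphere",
    "alpha_shape_volume",
    "critical_region",
    "path_profile",
    "minmax_normalize",
]

CRITICAL_STRAIN = 0.05


@dataclass(frozen=True)
class ROISpec:
    """Region of interest: tissue within 500 um of the probe tip plane.

    The default is the axial slab z in [-0.5, 0.5] mm (including the tissue
    below the tip); ``mode="ball"`` instead selects a hemispherical-ball
    neighborhood |x - tip| <= radius.  Nodes above ``exclude_z_above`` are
    always excluded (outliers next to the fixed top boundary).
    """

    z_min: float = -0.5
    z_max: float = 0.5
    exclude_z_above: float = 2.9
    mode: str = "slab"
    radius: float = 0.5
    tip: tuple = (0.0, 0.0, 0.0)

    def mask(self, nodes: np.ndarray) -> np.ndarray:
        if self.mode == "slab":
            m = (nodes[:, 2] >= self.z_min) & (nodes[:, 2] <= self.z_max)
        elif self.mode == "ball":
            m = np.linalg.norm(nodes - np.asarray(self.tip), axis=1) <= self.radius
        else:
            raise ValueError(f"unknown ROI mode {self.mode!r}")
        return m & (nodes[:, 2] <= self.exclude_z_above)


@dataclass
class CriticalRegion:
    """Point set above the critical-strain threshold and its alpha-shape volume."""

    threshold: float
    points: np.ndarray
    alpha: float
    volume: float  # mm^3


def _voigt_to_tensor(v):
    v = np.asarray(v, dtype=float)
    t = np.empty(v.shape[:-1] + (3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = v[..., 0], v[..., 1], v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5]
    return t


def equivalent_strain(strain, effective_poisson: float = 0.5, atol: float = 1e-8):
    """Equivalent (von Mises effective) strain of a strain tensor.

    ``strain``: (..., 3, 3) symmetric tensors or (..., 6) Voigt vectors
    (xx, yy, zz, xy, yz, xz; tensor shear).  nu' = 0.5 treats the tissue as
    incompressible, matching the deviatoric character of the measure.
    """
    strain = np.asarray(strain, dtype=float)
    if strain.shape[-1] == 6:
        t = _voigt_to_tensor(strain)
    else:
        t = strain
        if np.any(np.abs(t - np.swapaxes(t, -1, -2)) > atol):
            raise ValueError("strain tensor is not symmetric within tolerance")
    e = np.linalg.eigvalsh(t)
    d = (
        (e[..., 0] - e[..., 1]) ** 2
        + (e[..., 1] - e[..., 2]) ** 2
        + (e[..., 2] - e[..., 0]) ** 2
    )
    out = np.sqrt(0.5 * d) / (1.0 + effective_poisson)
    return out if out.ndim else float(out)


def _tissue_mask(mesh: geo.Mesh) -> np.ndarray:
    return mesh.tissue_nodes_mask()


def roi_strain_timeseries(history, mesh: geo.Mesh, roi: ROISpec = ROISpec(),
                          effective_poisson: float = 0.5):
    """(times, max-over-ROI, mean-over-ROI) equivalent strain series."""
    sel = _tissue_mask(mesh) & roi.mask(mesh.nodes)
    if not np.any(sel):
        raise ValueError("ROI contains no tissue nodes")
    eq = equivalent_strain(history.nodal_strain[:, sel, :], effective_poisson)
    return history.times, eq.max(axis=1), eq.mean(axis=1)


def peak_strain_field(history, mesh: geo.Mesh, exclude_z_above: float = 2.9,
                      effective_poisson: float = 0.5) -> np.ndarray:
    """Per-node maximum equivalent strain over the simulated period.

    Returns (N,) with NaN at probe nodes and at tissue nodes above the
    exclusion plane (the asymmetric outliers next to the fixed boundary).
    """
    if history.nodal_strain.shape[0] < 1:
        raise ValueError("history holds no saved steps")
    eq = equivalent_strain(history.nodal_strain, effective_poisson)  # (T, N)
    peak = eq.max(axis=0)
    out = np.full(mesh.n_nodes, np.nan)
    keep = _tissue_mask(mesh) & (mesh.nodes[:, 2] <= exclude_z_above)
    out[keep] = peak[keep]
    return out


def critical_points(peak_field: np.ndarray, mesh: geo.Mesh,
                    threshold: float = CRITICAL_STRAIN,
                    roi: ROISpec = ROISpec()) -> np.ndarray:
    """Coordinates of ROI nodes whose peak equivalent strain >= threshold."""
    ok = np.isfinite(peak_field) & roi.mask(mesh.nodes)
    return mesh.nodes[ok & (peak_field >= threshold)]


def _circumsphere(support) -> tuple[np.ndarray, float]:
    """Smallest sphere through 1-4 support points.

    The center is constrained to the affine span of the support (midpoint
    for 2 points, in-plane circumcenter for 3, circumcenter for 4).
    """
    sup = np.asarray(support, dtype=float)
    if len(sup) == 1:
        return sup[0].copy(), 0.0
    a = sup[0]
    V = sup[1:] - a  # (k, 3), center c = a + V^T y
    G = 2.0 * V @ V.T
    rhs = np.einsum("ij,ij->i", V, V)
    y, *_ = np.linalg.lstsq(G, rhs, rcond=None)
    c = a + V.T @ y
    return c, float(np.linalg.norm(c - a))


def smallest_enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum enclosing sphere of a 3D point set (Welzl, deterministic).

    Uses the incremental formulation: whenever a point falls outside the
    current sphere it joins the support set, recursing down to at most four
    boundary points.  The input permutation is fixed by a seeded RNG so the
    result is reproducible.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return np.zeros(3), 0.0
    pts = pts[np.random.default_rng(0).permutation(len(pts))]

    def outside(p, c, r):
        return np.linalg.norm(p - c) > r * (1.0 + 1e-12) + 1e-14

    c, r = _circumsphere(pts[:1])
    for i in range(1, len(pts)):
        if not outside(pts[i], c, r):
            continue
        c, r = _circumsphere(pts[i : i + 1])
        for j in range(i):
            if not outside(pts[j], c, r):
                continue
            c = 0.5 * (pts[i] + pts[j])
            r = float(np.linalg.norm(pts[i] - c))
            for k in range(j):
                if not outside(pts[k], c, r):
                    continue
                c, r = _circumsphere([pts[i], pts[j], pts[k]])
                for m in range(k):
                    if not outside(pts[m], c, r):
                        continue
                    c, r = _circumsphere([pts[i], pts[j], pts[k], pts[m]])
    return c, r


def _tet_circumradius(p):
    """Circumradius of tetrahedra p: (T, 4, 3); inf for degenerate tets."""
    a = p[:, 0]
    A = 2.0 * (p[:, 1:] - a[:, None])  # (T, 3, 3)
    b = np.sum(p[:, 1:] ** 2, axis=2) - np.sum(a**2, axis=1)[:, None]
    det = np.linalg.det(A)
    r = np.full(len(p), np.inf)
    ok = np.abs(det) > 1e-14
    if np.any(ok):
        c = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(c - a[ok], axis=1)
    return r


_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TET_FACES = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]


def _tet_min_enclosing_radius(p):
    """Radius of the smallest ball enclosing each tetrahedron, (T,).

    Candidates are the 6 edge-diameter balls, the 4 face circumcircle
    balls and the circumsphere; the smallest candidate that contains all
    four vertices is the minimum enclosing ball (Welzl support sets).
    Unlike the circumradius this stays bounded for sliver tetrahedra.
    """
    T = len(p)
    best = _tet_circumradius(p)
    tol = 1.0 + 1e-9
    for i, j in _TET_EDGES:
        c = 0.5 * (p[:, i] + p[:, j])
        r = 0.5 * np.linalg.norm(p[:, i] - p[:, j], axis=1)
        d = np.linalg.norm(p - c[:, None], axis=2).max(axis=1)
        ok = d <= r * tol + 1e-15
        best = np.where(ok, np.minimum(best, r), best)
    for i, j, k in _TET_FACES:
        a, b, cc = p[:, i], p[:, j], p[:, k]
        ab, ac = b - a, cc - a
        n = np.cross(ab, ac)
        n2 = np.einsum("ti,ti->t", n, n)
        safe = n2 > 1e-28
        # circumcenter of the triangle in its plane
        c = a + (
            np.einsum("ti,ti->t", ab, ab)[:, None] * np.cross(ac, n)
            + np.einsum("ti,ti->t", ac, ac)[:, None] * np.cross(n, ab)
        ) / np.where(safe, 2.0 * n2, 1.0)[:, None]
        r = np.linalg.norm(c - a, axis=1)
        d = np.linalg.norm(p - c[:, None], axis=2).max(axis=1)
        ok = safe & (d <= r * tol + 1e-15)
        best = np.where(ok, np.minimum(best, r), best)
    return best


def alpha_shape_volume(points: np.ndarray, alpha: float | None = None,
                       mesh: geo.Mesh | None = None) -> float:
    """Volume (mm^3) of the alpha shape of a 3D point set.

    With ``alpha=None`` the radius rule is applied: the smaller of the
    smallest-enclosing-sphere radius of the points and the maximum element
    characteristic length of ``mesh``.  The shape is the union of Delaunay
    tetrahedra whose smallest enclosing ball has radius <= alpha.  (For
    well-shaped tetrahedra this coincides with the circumradius criterion;
    for slivers it stays bounded, so the shape equals the convex hull
    whenever alpha reaches the point set's enclosing radius.)  Fewer than
    4 non-coplanar points give volume 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        return 0.0
    if alpha is None:
        _, r_enc = smallest_enclosing_sphere(pts)
        if mesh is None:
            raise ValueError("mesh required to apply the alpha radius rule")
        alpha = min(r_enc, geo.max_characteristic_length(mesh))
    try:
        tri = Delaunay(pts)
    except QhullError:
        return 0.0  # degenerate (coplanar/collinear) point set
    tets = pts[tri.simplices]
    r = _tet_min_enclosing_radius(tets)
    keep = r <= alpha * (1.0 + 1e-9)
    if not np.any(keep):
        return 0.0
    v = np.abs(np.linalg.det(tets[keep, 1:] - tets[keep, :1])) / 6.0
    return float(v.sum())


def critical_region(peak_field: np.ndarray, mesh: geo.Mesh,
                    threshold: float = CRITICAL_STRAIN,
                    roi: ROISpec = ROISpec()) -> CriticalRegion:
    """Critical region in the ROI and its alpha-shape volume.

    An element counts as critical when any of its nodes' peak equivalent
    strain reaches the threshold ("critical strain at least once"); the
    alpha shape is built over the centroids of those tissue elements whose
    centroid lies in the ROI.
    """
    node_crit = np.isfinite(peak_field) & (peak_field >= threshold)
    tis = mesh.hexes[mesh.region == 0]
    elem_crit = node_crit[tis].any(axis=1)
    centroids = mesh.nodes[tis].mean(axis=1)
    sel = elem_crit & roi.mask(centroids)
    pts = centroids[sel]
    if len(pts) < 4:
        return CriticalRegion(threshold, pts, 0.0, 0.0)
    _, r_enc = smallest_enclosing_sphere(pts)
    alpha = min(r_enc, geo.max_characteristic_length(mesh))
    vol = alpha_shape_volume(pts, alpha=alpha)
    return CriticalRegion(threshold, pts, float(alpha), vol)


_PATH_Z = {"top": 2.9, "mid": 1.5, "tip": 0.0}


def path_profile(peak_field: np.ndarray, mesh: geo.Mesh, path: str | float,
                 section: geo.ProbeCrossSection | None = None,
                 n_grid: int = 0):
    """Side-averaged peak-strain profile along the x = y diagonal of a plane.

    ``path``: "top" (z = 2.9), "mid" (1.5), "tip" (0.0) or an explicit z.
    Tissue nodes on the plane lying on the diagonal are folded by distance
    from the probe surface (section boundary) and the two sides averaged on
    a common distance grid.  Returns (distance_um_free grid in mm, strain).
    """
    z0 = _PATH_Z.get(path, path) if isinstance(path, str) else float(path)
    if isinstance(path, str) and path not in _PATH_Z:
        raise ValueError(f"unknown path {path!r}")
    nodes = mesh.nodes
    zmin, zmax = nodes[:, 2].min(), nodes[:, 2].max()
    if not (zmin - 1e-9 <= z0 <= zmax + 1e-9):
        raise ValueError(f"path plane z = {z0} outside the domain")
    on_plane = np.abs(nodes[:, 2] - z0) < 1e-9
    on_diag = np.abs(nodes[:, 0] - nodes[:, 1]) < 1e-9
    ok = on_plane & on_diag & np.isfinite(peak_field)
    if section is not None:
        poly = section.polygon(256)
        inside = np.array(
            [poly.contains(Point(x, y)) for x, y in nodes[ok][:, :2]]
        )
        boundary = poly.exterior
        dist = np.array(
            [boundary.distance(Point(x, y)) for x, y in nodes[ok][:, :2]]
        )
    else:
        inside = np.zeros(int(ok.sum()), dtype=bool)
        dist = np.hypot(nodes[ok, 0], nodes[ok, 1])
    ids = np.where(ok)[0][~inside]
    dist = dist[~inside]
    side = np.sign(nodes[ids, 0] + nodes[ids, 1])
    vals = peak_field[ids]
    profiles = []
    for s in (-1.0, 1.0):
        m = side == s
        if not np.any(m):
            continue
        o = np.argsort(dist[m])
        profiles.append((dist[m][o], vals[m][o]))
    if not profiles:
        raise ValueError("no diagonal nodes found on the path plane")
    dmax = min(p[0][-1] for p in profiles)
    if n_grid:
        grid = np.linspace(0.0, dmax, n_grid)
    else:
        grid = np.unique(np.concatenate([p[0][p[0] <= dmax + 1e-12]
                                         for p in profiles]))
    avg = np.mean([np.interp(grid, d, v) for d, v in profiles], axis=0)
    return grid, avg


def minmax_normalize(series, mode: str = "minmax"):
    """Normalize a series to [0, 1] (min-max) or to max = 1 (max mode)."""
    x = np.asarray(series, dtype=float)
    if mode == "minmax":
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi - lo <= 0.0:
            raise ValueError("constant series cannot be min-max normalized")
        return (x - lo) / (hi - lo)
    if mode == "max":
        hi = np.nanmax(np.abs(x))
        if hi == 0.0:
            raise ValueError("all-zero series cannot be max normalized")
        return x / hi
    raise ValueError(f"unknown normalization mode {mode!r}")
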