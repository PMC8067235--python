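"""Probe/tissue domain construction and hexahedral meshing.

The domain is a 1 x 1 x 6 mm brain-tissue block (coordinates in mm, tissue
occupying z in [-3, 3]) with a probe of length 3 mm embedded along z in
[0, 3]; the probe tip plane is z = 0 and a probe-shaped void runs through
the upper half of the tissue.  All cross-sections are normalized to the
area of the reference 400-um-diameter circle, S = 0.04*pi mm^2, so that
cross-sectional shape and aspect ratio can be varied as controlled factors.

Meshing uses a structured butterfly (O-grid) scheme: the cross-section
interior is a Coons-patch core plus transition rings, the tissue annulus is
a set of radially graded quad rings between the section boundary and the
outer square, and both footprints are extruded along z.  Probe and tissue
are separate bodies whose surface discretizations coincide node-for-node in
the reference configuration, which the frictional contact model relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "DomainSpec",
    "ProbeCrossSection",
    "Mesh",
    "MeshError",
    "build_cross_section",
    "generate_domain_mesh",
    "mesh_preset",
    "max_characteristic_length",
    "mesh_quality_report",
]

REFERENCE_AREA = 0.04 * math.pi  # mm^2, area of a d = 400 um circle

SECTION_KINDS = ("ellipse", "square", "rounded_square", "octagon")


class MeshError(RuntimeError):
    """Raised when mesh construction fails or an invalid mesh is supplied."""


@dataclass(frozen=True)
class DomainSpec:
    """Tissue block and probe dimensions (mm)."""

    width: float = 1.0
    thickness: float = 1.0
    depth: float = 6.0
    probe_length: float = 3.0
    tip_z: float = 0.0  # probe tip plane; tissue spans [tip_z - depth/2, ...]

    @property
    def z_bottom(self) -> float:
        return self.tip_z - self.depth / 2.0

    @property
    def z_top(self) -> float:
        return self.tip_z + self.depth / 2.0


# ---------------------------------------------------------------------------
# cross-sections


@dataclass(frozen=True)
class ProbeCrossSection:
    """Closed planar cross-section of the probe, centered at the origin.

    ``kind`` is one of ellipse / square / rounded_square / octagon; ellipses
    additionally carry an integer aspect ``ratio`` (1:ratio, long axis along
    y).  The enclosed area equals ``area`` exactly by construction.
    """

    kind: str
    area: float = REFERENCE_AREA
    ratio: int = 1
    # four quarters (starting at the 45-deg corner direction, CCW), each a
    # tuple of (m, 2) sub-curve polylines
    _quarters: tuple = field(repr=False, default=())

    def polygon(self, resolution: int = 128) -> Polygon:
        """Shapely polygon of the boundary (resolution points per quarter)."""
        pts = self.boundary_points(resolution)
        return Polygon(pts)

    def boundary_points(self, n_per_quarter: int) -> np.ndarray:
        """(4n, 2) CCW boundary points starting at the 45-degree corner.

        Each quarter is resampled by arc length with ``n_per_quarter``
        segments; geometric vertices (polygon corners, arc-flat junctions)
        are preserved whenever n allows, so coarse polygonal sections keep
        their corners sharp.
        """
        quarters = [_resample_quarter(q, n_per_quarter) for q in self._quarters]
        return np.vstack([q[:-1] for q in quarters])

    def radius_at(self, angle: float) -> float:
        """Distance from the center to the boundary along ``angle`` (rad)."""
        pts = self.boundary_points(256)
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        r = np.hypot(pts[:, 0], pts[:, 1])
        d = np.angle(np.exp(1j * (ang - angle)))
        return float(r[np.argmin(np.abs(d))])


def _arc(c, r, a0, a1, m=64) -> np.ndarray:
    t = np.linspace(a0, a1, m)
    return np.column_stack([c[0] + r * np.cos(t), c[1] + r * np.sin(t)])


def _polyline_length(p: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))


def _resample_by_arclength(p: np.ndarray, n: int) -> np.ndarray:
    seg = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n + 1)
    x = np.interp(t, s, p[:, 0])
    y = np.interp(t, s, p[:, 1])
    return np.column_stack([x, y])


def _resample_quarter(curves: tuple, n: int) -> np.ndarray:
    """Resample a quarter (list of sub-curves) into n segments, keeping the
    junction vertices between sub-curves when n >= number of sub-curves."""
    curves = [np.asarray(c, dtype=float) for c in curves]
    if n < len(curves):
        whole = np.vstack([c[:-1] for c in curves] + [curves[-1][-1:]])
        return _resample_by_arclength(whole, n)
    lengths = np.array([_polyline_length(c) for c in curves])
    # largest-remainder allocation of n segments, >= 1 per sub-curve
    raw = lengths / lengths.sum() * n
    counts = np.maximum(1, np.floor(raw).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts - raw)] -= 1
    while counts.sum() < n:
        counts[np.argmin(counts - raw)] += 1
    parts = [_resample_by_arclength(c, k) for c, k in zip(curves, counts)]
    return np.vstack([p[:-1] for p in parts] + [parts[-1][-1:]])


def build_cross_section(
    kind: str, area: float = REFERENCE_AREA, ratio: int = 1
) -> ProbeCrossSection:
    """Construct a probe cross-section of the requested kind and area.

    The composite shapes follow the plus-sign construction: five squares of
    side c with the four corners completed by right isoceles triangles
    (octagon, area 7 c^2) or by quarter circles (rounded square, area
    (5 + pi) c^2); c is solved from the area constraint.
    """
    if kind not in SECTION_KINDS:
        raise ValueError(f"unknown cross-section kind {kind!r}; valid: {SECTION_KINDS}")
    if area <= 0.0:
        raise ValueError("area must be positive")
    if ratio != 1 and kind != "ellipse":
        raise ValueError("aspect ratio is only supported for ellipse sections")
    if kind == "ellipse":
        if ratio not in (1, 2, 3):
            raise ValueError("ellipse aspect ratio must be 1, 2 or 3")
        a = math.sqrt(area / (math.pi * ratio))  # semi-axis along x
        b = a * ratio  # long axis along y
        quarters = []
        for k in range(4):
            t = np.linspace(math.pi / 4.0 + k * math.pi / 2.0,
                            3.0 * math.pi / 4.0 + k * math.pi / 2.0, 257)
            quarters.append(
                (np.column_stack([a * np.cos(t), b * np.sin(t)]),)
            )
        return ProbeCrossSection(kind=kind, area=area, ratio=ratio,
                                 _quarters=tuple(quarters))
    if kind == "square":
        s = math.sqrt(area) / 2.0
        quarter = (np.array([[s, s], [-s, s]]),)
    elif kind == "octagon":
        c = math.sqrt(area / 7.0)
        h = 0.5 * c
        # quarter from the NE hypotenuse midpoint (c, c)/sqrt2-scaled: the
        # hypotenuse runs (1.5c, 0.5c) -> (0.5c, 1.5c); its midpoint (c, c)
        # lies on the 45-degree direction.
        quarter = (
            np.array([[c, c], [h, 3 * h]]),
            np.array([[h, 3 * h], [-h, 3 * h]]),
            np.array([[-h, 3 * h], [-c, c]]),
        )
    else:  # rounded_square
        c = math.sqrt(area / (5.0 + math.pi))
        h = 0.5 * c
        quarter = (
            _arc((h, h), c, math.pi / 4.0, math.pi / 2.0),
            np.array([[h, 3 * h], [-h, 3 * h]]),
            _arc((-h, h), c, math.pi / 2.0, 3.0 * math.pi / 4.0),
        )
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 deg
    quarters = [tuple(quarter)]
    for _ in range(3):
        quarters.append(tuple(c @ rot.T for c in quarters[-1]))
    return ProbeCrossSection(kind=kind, area=area, ratio=ratio,
                             _quarters=tuple(quarters))


# ---------------------------------------------------------------------------
# mesh container


@dataclass
class Mesh:
    """Two-body (tissue + probe) hexahedral mesh with tagged facet sets.

    nodes : (N, 3) coordinates, mm
    hexes : (E, 8) connectivity, VTK hexahedron ordering
    region : (E,) int8, 0 = tissue, 1 = probe
    facet_sets : name -> (F, 4) quad connectivity.  Names: probe_top,
        probe_surface (contact target: enclosure + bottom), tissue_void_wall
        (contact side), tissue_lateral, tissue_bottom, tissue_top.
    contact pairs : coincident (tissue node, probe node) index pairs with
        outward (probe -> tissue) reference normals and lumped nodal areas.
    """

    nodes: np.ndarray
    hexes: np.ndarray
    region: np.ndarray
    facet_sets: dict[str, np.ndarray]
    contact_tissue_nodes: np.ndarray
    contact_probe_nodes: np.ndarray
    contact_normals: np.ndarray
    contact_areas: np.ndarray
    bulk_size: float = 0.0
    contact_size: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.hexes)

    def element_volumes(self) -> np.ndarray:
        return _hex_volumes(self.nodes, self.hexes)

    def tissue_nodes_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.hexes[self.region == 0])] = True
        return mask


_GAUSS_1D = np.array([-1.0, 1.0]) / math.sqrt(3.0)


def _hex_shape_gradients(xi):
    """d N_a / d xi at a point xi in the bi-unit cube; (8, 3)."""
    s = np.array(
        [
            [-1, -1, -1],
            [1, -1, -1],
            [1, 1, -1],
            [-1, 1, -1],
            [-1, -1, 1],
            [1, -1, 1],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=float,
    )
    g = np.empty((8, 3))
    for a in range(8):
        sa = s[a]
        g[a, 0] = sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 1] = sa[1] * (1 + sa[0] * xi[0]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 2] = sa[2] * (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1]) / 8.0
    return g


def hex_gauss_points():
    """(8, 3) Gauss points and the (8, 3) shape-gradient stack per point."""
    pts = np.array(
        [[x, y, z] for z in _GAUSS_1D for y in _GAUSS_1D for x in _GAUSS_1D]
    )
    grads = np.stack([_hex_shape_gradients(p) for p in pts])
    return pts, grads


_GP, _GRADS = None, None


def _gauss():
    global _GP, _GRADS
    if _GP is None:
        _GP, _GRADS = hex_gauss_points()
    return _GP, _GRADS


def _hex_volumes(nodes, hexes):
    _, grads = _gauss()
    coords = nodes[hexes]  # (E, 8, 3)
    vol = np.zeros(len(hexes))
    for g in grads:
        J = np.einsum("eai,aj->eij", coords, g)
        vol += np.linalg.det(J)
    return vol


_HEX_EDGES = np.array(
    [
        [0, 1], [1, 2], [2, 3], [3, 0],
        [4, 5], [5, 6], [6, 7], [7, 4],
        [0, 4], [1, 5], [2, 6], [3, 7],
    ]
)


def max_characteristic_length(mesh: Mesh) -> float:
    """Maximum element characteristic length, longest-edge convention.

    The characteristic length of a hexahedron is taken as its longest edge
    (face/body diagonals excluded); the mesh value is the maximum over all
    elements.  Used by the alpha-shape radius rule.
    """
    if mesh.n_elements == 0:
        raise MeshError("empty mesh")
    coords = mesh.nodes[mesh.hexes]  # (E, 8, 3)
    e = coords[:, _HEX_EDGES[:, 1]] - coords[:, _HEX_EDGES[:, 0]]
    return float(np.max(np.linalg.norm(e, axis=-1)))


def mesh_quality_report(mesh: Mesh) -> dict:
    """Scaled-Jacobian and edge-aspect metrics; used to gate solver runs."""
    coords = mesh.nodes[mesh.hexes]
    edges = coords[:, _HEX_EDGES[:, 1]] - coords[:, _HEX_EDGES[:, 0]]
    elen = np.linalg.norm(edges, axis=-1)
    aspect = elen.max(axis=1) / elen.min(axis=1)
    # corner scaled Jacobians: normalized determinant of the three edges
    # meeting at each corner, oriented right-handed for a regular hex
    bottom, top = [0, 1, 2, 3], [4, 5, 6, 7]
    sj = np.full((mesh.n_elements, 8), np.inf)

    def unit(vecs):
        return vecs / np.linalg.norm(vecs, axis=-1, keepdims=True)

    for c in range(8):
        if c in bottom:
            nxt = bottom[(bottom.index(c) + 1) % 4]
            prv = bottom[(bottom.index(c) - 1) % 4]
            triple = (nxt, prv, c + 4)
        else:
            nxt = top[(top.index(c) + 1) % 4]
            prv = top[(top.index(c) - 1) % 4]
            triple = (prv, nxt, c - 4)
        p = coords[:, c]
        a = unit(coords[:, triple[0]] - p)
        b = unit(coords[:, triple[1]] - p)
        d = unit(coords[:, triple[2]] - p)
        sj[:, c] = np.einsum("ei,ei->e", np.cross(a, b), d)
    sj_min = sj.min(axis=1)
    return {
        "n_elements": mesh.n_elements,
        "n_nodes": mesh.n_nodes,
        "min_scaled_jacobian": float(sj_min.min()),
        "mean_scaled_jacobian": float(sj_min.mean()),
        "max_aspect_ratio": float(aspect.max()),
        # corners that are exactly flat (sj = 0) occur legitimately where a
        # structured block corner sits on a straight boundary segment; only
        # strictly negative corner Jacobians indicate inversion
        "n_inverted": int(np.sum(sj_min < -1e-12)),
    }


# ---------------------------------------------------------------------------
# footprint (2D) meshing


def _coons_patch(bottom, right, top, left):
    """Transfinite interpolation; edges are (n+1, 2) polylines of the unit
    square image: bottom u->, right v->, top u-> (at v=1), left v-> (at u=0).
    Returns (n+1, n+1, 2) grid indexed [iu, iv]."""
    n = len(bottom) - 1
    u = np.linspace(0.0, 1.0, n + 1)[:, None, None]
    v = np.linspace(0.0, 1.0, n + 1)[None, :, None]
    b = bottom[:, None, :]
    t = top[:, None, :]
    le = left[None, :, :]
    r = right[None, :, :]
    c00, c10, c01, c11 = bottom[0], bottom[-1], top[0], top[-1]
    grid = (
        (1 - v) * b + v * t + (1 - u) * le + u * r
        - ((1 - u) * (1 - v) * c00 + u * (1 - v) * c10
           + (1 - u) * v * c01 + u * v * c11)
    )
    return grid


class _Footprint:
    """Structured 2D mesh of the unit-square tissue cross-section.

    Nodes are ordered: interior (core + transition) first, then the section
    boundary ring, then the outer ring layers.  Quads carry an
    ``inside_section`` flag.  The section boundary nodes are shared between
    the interior mesh and ring layer 0.
    """

    def __init__(self, section: ProbeCrossSection, width: float, n: int,
                 n_rings: int, ring_growth: float, n_transition: int = 2,
                 core_scale: float = 0.45):
        M = 4 * n
        S = section.boundary_points(n)  # (M, 2) on the section boundary
        # outer square boundary, quarter corner-to-corner CCW from (w, w)
        w = width / 2.0
        corners = np.array([[w, w], [-w, w], [-w, -w], [w, -w], [w, w]])
        Q = []
        for k in range(4):
            seg = np.linspace(corners[k], corners[k + 1], n + 1)[:-1]
            Q.append(seg)
        Q = np.vstack(Q)  # (M, 2)

        core_b = core_scale * S  # core boundary, scaled copy of the section

        # --- core grid via Coons patch; patch corners at 225/315/45/135 deg
        def quarter(pts, k):
            idx = (np.arange(n + 1) + k * n) % M
            return pts[idx]

        bottom = quarter(core_b, 2)  # 225 -> 315
        right = quarter(core_b, 3)  # 315 -> 45
        top = quarter(core_b, 1)[::-1]  # 135 -> 45 reversed: 45->135 rev
        left = quarter(core_b, 2)[::-1]  # placeholder, fixed below
        # left edge: from 225 (u=0,v=0) up to 135 (u=0,v=1): reversed quarter 1
        left = quarter(core_b, 1)[::-1]
        top = quarter(core_b, 0)[::-1]
        grid = _coons_patch(bottom, right, top, left)  # [iu, iv]

        nodes = []
        node_id = {}

        def add(p):
            key = len(nodes)
            nodes.append(p)
            return key

        core_ids = np.empty((n + 1, n + 1), dtype=int)
        for iu in range(n + 1):
            for iv in range(n + 1):
                core_ids[iu, iv] = add(grid[iu, iv])

        quads = []
        inside = []
        for iu in range(n):
            for iv in range(n):
                quads.append(
                    (core_ids[iu, iv], core_ids[iu + 1, iv],
                     core_ids[iu + 1, iv + 1], core_ids[iu, iv + 1])
                )
                inside.append(True)

        # core boundary as a CCW cycle starting at 45 deg (iu=n, iv=n corner)
        cyc = []
        for iu in range(n, 0, -1):
            cyc.append(core_ids[iu, n])  # 45 -> 135 along top (u decreasing)
        for iv in range(n, 0, -1):
            cyc.append(core_ids[0, iv])  # 135 -> 225 down left
        for iu in range(0, n):
            cyc.append(core_ids[iu, 0])  # 225 -> 315 along bottom
        for iv in range(0, n):
            cyc.append(core_ids[n, iv])  # 315 -> 45 up right
        core_cycle = np.array(cyc)
        assert len(core_cycle) == M

        # --- transition rings core boundary -> section boundary
        prev_cycle = core_cycle
        for layer in range(1, n_transition + 1):
            t = layer / n_transition
            ring_ids = []
            for j in range(M):
                p = (1 - t) * core_b[j] + t * S[j]
                ring_ids.append(add(p))
            ring_ids = np.array(ring_ids)
            for j in range(M):
                jp = (j + 1) % M
                quads.append((prev_cycle[j], prev_cycle[jp],
                              ring_ids[jp], ring_ids[j]))
                inside.append(True)
            prev_cycle = ring_ids
        self.section_boundary = prev_cycle  # node ids on the section curve

        # --- outer rings section boundary -> square, geometric grading
        g = ring_growth
        steps = g ** np.arange(n_rings)
        tpos = np.concatenate([[0.0], np.cumsum(steps)]) / np.sum(steps)
        for layer in range(1, n_rings + 1):
            t = tpos[layer]
            ring_ids = []
            for j in range(M):
                p = (1 - t) * S[j] + t * Q[j]
                ring_ids.append(add(p))
            ring_ids = np.array(ring_ids)
            for j in range(M):
                jp = (j + 1) % M
                quads.append((prev_cycle[j], prev_cycle[jp],
                              ring_ids[jp], ring_ids[j]))
                inside.append(False)
            prev_cycle = ring_ids
        self.outer_boundary = prev_cycle

        self.nodes = np.array(nodes)
        self.quads = np.array(quads, dtype=int)
        self.inside = np.array(inside, dtype=bool)
        self.M = M
        self.n = n
        # fix quad orientation to CCW (positive area)
        p = self.nodes[self.quads]
        area2 = np.zeros(len(self.quads))
        for k in range(4):
            a, b = p[:, k], p[:, (k + 1) % 4]
            area2 += a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]
        flip = area2 < 0
        self.quads[flip] = self.quads[flip][:, ::-1]

        # node classification
        self.section_nodes = np.unique(self.quads[self.inside])  # incl. bdry


def _grade_z_planes(spec: DomainSpec, fine: float, coarse: float) -> np.ndarray:
    """z planes over the tissue depth, fine near the tip plane, forced
    planes at the tip, ROI limits and the path/exclusion planes."""
    forced = np.array(
        [spec.z_bottom, -0.5, 0.0, 0.5, 1.5, 2.9, spec.z_top]
    )

    def size_at(z):
        d = abs(z)
        return fine + (coarse - fine) * min(1.0, max(0.0, (d - 0.5)) / 1.2)

    zs = []
    for z0, z1 in zip(forced[:-1], forced[1:]):
        mid = 0.5 * (z0 + z1)
        nseg = max(1, int(round((z1 - z0) / size_at(mid))))
        zs.append(np.linspace(z0, z1, nseg + 1)[:-1])
    zs.append(forced[-1:])
    return np.concatenate(zs)


def mesh_preset(name: str) -> dict:
    """Named discretization presets (sizes in mm).

    ``reduced`` is the desk-scale default (bulk 160 um, contact 60 um);
    ``tiny`` is for fast property checks; ``fine`` refines toward the
    reference discretization for convergence checks.
    """
    presets = {
        "tiny": dict(bulk_size=0.30, contact_size=0.10),
        "reduced": dict(bulk_size=0.16, contact_size=0.06),
        "fine": dict(bulk_size=0.11, contact_size=0.04),
        "reference": dict(bulk_size=0.08, contact_size=0.0235),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; valid: {sorted(presets)}")
    return presets[name]


def generate_domain_mesh(
    spec: DomainSpec,
    section: ProbeCrossSection,
    bulk_size: float,
    contact_size: float,
) -> Mesh:
    """Build the conforming two-body tissue + probe mesh.

    ``bulk_size`` controls far-field element size, ``contact_size`` the
    refined size at the contact interface (first radial ring layer and
    circumferential spacing).  The probe surface and the tissue void wall
    are discretized identically and node pairs coincide at t = 0.
    """
    if bulk_size <= 0 or contact_size <= 0 or contact_size > bulk_size:
        raise MeshError("need 0 < contact_size <= bulk_size")
    perimeter = section.polygon(256).exterior.length
    n = max(3, int(round(perimeter / 4.0 / (2.0 * contact_size))))
    # radial rings: gap from section to outer square, geometric growth
    gap = 0.5 * min(1.0, 1.0) - 0.0  # nominal half-width
    growth = 1.8
    # choose ring count so the first layer is ~contact_size on the mean gap
    mean_r = math.sqrt(section.area / math.pi)
    mean_gap = 0.5 - mean_r * 0.8
    n_rings = 2
    while n_rings < 12:
        first = mean_gap * (growth - 1.0) / (growth**n_rings - 1.0)
        if first <= contact_size * 1.2:
            break
        n_rings += 1
    fp = _Footprint(section, spec.width, n, n_rings, growth)

    zfine = min(2.0 * contact_size, bulk_size)
    zs = _grade_z_planes(spec, zfine, 2.0 * bulk_size)
    nz = len(zs)
    i_tip = int(np.argmin(np.abs(zs - spec.tip_z)))
    if abs(zs[i_tip] - spec.tip_z) > 1e-12:
        raise MeshError("tip plane missing from z grading")

    n2 = len(fp.nodes)
    sec_nodes = fp.section_nodes  # interior incl. boundary
    bdry = fp.section_boundary
    bdry_set = set(bdry.tolist())
    annulus_nodes = np.unique(fp.quads[~fp.inside])  # ring nodes incl. bdry

    # ---- global node numbering
    nodes = []
    tissue_map = {}  # (iz, fp_node) -> gid
    probe_map = {}

    def t_gid(iz, a):
        key = (iz, a)
        gid = tissue_map.get(key)
        if gid is None:
            gid = len(nodes)
            nodes.append((fp.nodes[a, 0], fp.nodes[a, 1], zs[iz]))
            tissue_map[key] = gid
        return gid

    def p_gid(iz, a):
        key = (iz, a)
        gid = probe_map.get(key)
        if gid is None:
            gid = len(nodes)
            nodes.append((fp.nodes[a, 0], fp.nodes[a, 1], zs[iz]))
            probe_map[key] = gid
        return gid

    hexes = []
    region = []
    quad_in = fp.quads[fp.inside]
    quad_out = fp.quads[~fp.inside]

    for iz in range(nz - 1):
        # tissue ring elements at all layers
        for q in quad_out:
            hexes.append(
                [t_gid(iz, q[0]), t_gid(iz, q[1]), t_gid(iz, q[2]), t_gid(iz, q[3]),
                 t_gid(iz + 1, q[0]), t_gid(iz + 1, q[1]), t_gid(iz + 1, q[2]),
                 t_gid(iz + 1, q[3])]
            )
            region.append(0)
        if iz + 1 <= i_tip:
            # tissue fills the section footprint below the tip
            for q in quad_in:
                hexes.append(
                    [t_gid(iz, q[0]), t_gid(iz, q[1]), t_gid(iz, q[2]),
                     t_gid(iz, q[3]), t_gid(iz + 1, q[0]), t_gid(iz + 1, q[1]),
                     t_gid(iz + 1, q[2]), t_gid(iz + 1, q[3])]
                )
                region.append(0)
        if iz >= i_tip:
            # probe occupies the section footprint above the tip
            for q in quad_in:
                hexes.append(
                    [p_gid(iz, q[0]), p_gid(iz, q[1]), p_gid(iz, q[2]),
                     p_gid(iz, q[3]), p_gid(iz + 1, q[0]), p_gid(iz + 1, q[1]),
                     p_gid(iz + 1, q[2]), p_gid(iz + 1, q[3])]
                )
                region.append(1)

    # NOTE: tissue section-boundary nodes above the tip belong to ring
    # elements only; tissue interior footprint nodes exist only at iz <= i_tip.

    nodes = np.array(nodes)
    hexes = np.array(hexes, dtype=int)
    region = np.array(region, dtype=np.int8)

    # ---- facet sets
    fs: dict[str, list] = {
        "probe_top": [], "probe_surface": [], "tissue_void_wall": [],
        "tissue_lateral": [], "tissue_bottom": [], "tissue_top": [],
    }
    M = fp.M
    iz_top = nz - 1
    for q in quad_in:
        fs["probe_top"].append([probe_map[(iz_top, a)] for a in q])
        fs["probe_surface"].append([probe_map[(i_tip, a)] for a in q])
        fs["tissue_void_wall"].append([tissue_map[(i_tip, a)] for a in q])
        fs["tissue_bottom"].append([tissue_map[(0, a)] for a in q])
    for q in quad_out:
        fs["tissue_bottom"].append([tissue_map[(0, a)] for a in q])
        fs["tissue_top"].append([tissue_map[(iz_top, a)] for a in q])
    for iz in range(nz - 1):
        for j in range(M):
            jp = (j + 1) % M
            a, b = bdry[j], bdry[jp]
            if iz >= i_tip:
                fs["probe_surface"].append(
                    [probe_map[(iz, a)], probe_map[(iz, b)],
                     probe_map[(iz + 1, b)], probe_map[(iz + 1, a)]]
                )
                fs["tissue_void_wall"].append(
                    [tissue_map[(iz, a)], tissue_map[(iz, b)],
                     tissue_map[(iz + 1, b)], tissue_map[(iz + 1, a)]]
                )
        for j in range(M):
            jp = (j + 1) % M
            a, b = fp.outer_boundary[j], fp.outer_boundary[jp]
            fs["tissue_lateral"].append(
                [tissue_map[(iz, a)], tissue_map[(iz, b)],
                 tissue_map[(iz + 1, b)], tissue_map[(iz + 1, a)]]
            )
    facet_sets = {k: np.array(v, dtype=int) for k, v in fs.items()}

    # ---- contact pairs (coincident reference nodes)
    pair_t, pair_p = [], []
    for iz in range(i_tip, nz):
        for a in bdry:
            pair_t.append(tissue_map[(iz, a)])
            pair_p.append(probe_map[(iz, a)])
    for a in sec_nodes:
        if a in bdry_set:
            continue
        pair_t.append(tissue_map[(i_tip, a)])
        pair_p.append(probe_map[(i_tip, a)])
    pair_t = np.array(pair_t, dtype=int)
    pair_p = np.array(pair_p, dtype=int)

    # normals / lumped areas from the probe-surface facets
    normals = np.zeros((len(pair_t), 3))
    areas = np.zeros(len(pair_t))
    probe_to_pair = {p: i for i, p in enumerate(pair_p)}
    surf = facet_sets["probe_surface"]
    pcoords = nodes[surf]
    # facet normal: outward from probe.  Wall facets were built CCW seen
    # from outside; bottom facets point down.
    v1 = pcoords[:, 1] - pcoords[:, 0]
    v2 = pcoords[:, 3] - pcoords[:, 0]
    fn = np.cross(v1, v2)
    fa = 0.5 * np.linalg.norm(
        np.cross(pcoords[:, 2] - pcoords[:, 0], pcoords[:, 3] - pcoords[:, 1]),
        axis=-1,
    )
    # orient outward: wall facets away from the z axis, bottom facets -z
    centers = pcoords.mean(axis=1)
    nrm = np.linalg.norm(fn, axis=-1, keepdims=True)
    fn = fn / np.where(nrm == 0.0, 1.0, nrm)
    is_bottom = np.abs(centers[:, 2] - spec.tip_z) < 1e-9
    sgn = np.where(
        is_bottom,
        -np.sign(fn[:, 2]),
        np.sign(np.einsum("fi,fi->f", fn[:, :2], centers[:, :2])),
    )
    sgn = np.where(sgn == 0.0, 1.0, sgn)
    fn = fn * sgn[:, None]
    for f in range(len(surf)):
        for a in surf[f]:
            i = probe_to_pair.get(a)
            if i is not None:
                normals[i] += fn[f] * fa[f]
                areas[i] += fa[f] / 4.0
    nn = np.linalg.norm(normals, axis=-1, keepdims=True)
    normals = normals / np.where(nn == 0.0, 1.0, nn)

    mesh = Mesh(
        nodes=nodes, hexes=hexes, region=region, facet_sets=facet_sets,
        contact_tissue_nodes=pair_t, contact_probe_nodes=pair_p,
        contact_normals=normals, contact_areas=areas,
        bulk_size=bulk_size, contact_size=contact_size,
    )
    vols = mesh.element_volumes()
    if np.any(vols <= 0.0):
        raise MeshError(
            f"mesh generation produced {int(np.sum(vols <= 0))} non-positive-"
            f"volume elements (kind={section.kind}, ratio={section.ratio})"
        )
    return mesh
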