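"""Synthetic inputs with known ground truth.

The study's raw confocal images are not deposited, so the histology
pipeline is exercised on synthetic 16-bit images that emulate their
structure: a low-intensity vertical probe track ending in a tip, a marker
intensity that decays with horizontal distance d from the track edge,

    I(x, y) = B (1 + A exp(-d / lambda_d)) + N(0, sigma),

clipped to the 16-bit range, with background level B, fold-change amplitude
A at the probe surface, decay length lambda_d and Gaussian noise sigma.
Group studies assign material-specific amplitudes ordered as the chronic
response magnitudes (steel > silica > PC > hydrogel).  All generators are
seed-deterministic.

Solver verification fixtures (single-element Ogden uniaxial tension, linear
patch test, Coulomb friction block, two-material bar) carry closed-form
references.  ``study_scenarios`` enumerates the full simulation sweep:
four probe materials at COF 0.3, the hydrogel COF sweep 0.1-0.9, and the
cross-section sweep (ellipse aspect ratios and shapes) at fixed area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fe_solver as fes
from . import geometry as geo
from . import materials as mat
from .histology_quant import FluorescenceImage

__all__ = [
    "IHCGroundTruth",
    "generate_ihc_image",
    "make_group_study",
    "box_mesh",
    "solver_fixture",
    "study_scenarios",
    "GROUP_AMPLITUDES",
]

# Material-specific fold-change amplitudes for the 4-week group study,
# ordered to mirror the chronic-response magnitudes (steel > silica > PC >
# hydrogel); values chosen as realistic fold changes over background.
GROUP_AMPLITUDES = {"steel": 3.0, "silica": 2.2, "PC": 1.5, "hydrogel": 0.7}


@dataclass(frozen=True)
class IHCGroundTruth:
    """Generative parameters of one synthetic IHC image."""

    background: float = 2000.0  # counts
    amplitude: float = 2.0  # fold change over background at the surface
    decay_um: float = 120.0  # decay length lambda_d
    noise_sd: float = 100.0  # counts
    track_width_um: float = 400.0
    seed: int = 0

    def __post_init__(self):
        if self.background <= 0 or self.amplitude < 0:
            raise ValueError("need background > 0 and amplitude >= 0")
        if self.decay_um <= 0 or self.noise_sd < 0:
            raise ValueError("need decay_um > 0 and noise_sd >= 0")


def generate_ihc_image(
    gt: IHCGroundTruth,
    shape: tuple[int, int] = (1500, 3000),
    pixel_size: float = 2.0,
    tip_center: tuple[int, int] | None = None,
    channel: str = "GFAP",
    material: str = "",
) -> tuple[FluorescenceImage, dict]:
    """Render one synthetic image and return it with its ground-truth record.

    ``shape`` is (rows, cols); the default 1500 x 3000 px at 2 um/px spans
    3 x 6 mm so every analysis rectangle fits.  The track is a vertical
    near-zero band of width ``track_width_um`` centered on the tip column,
    extending upward from the tip row.
    """
    rows, cols = shape
    if tip_center is None:
        tip_center = (int(rows * 0.75), cols // 2)
    trow, tcol = tip_center
    half_w = gt.track_width_um / 2.0 / pixel_size
    if 2 * half_w >= cols:
        raise ValueError("track wider than the image")
    rng = np.random.default_rng(gt.seed)
    c = np.arange(cols, dtype=float)
    # horizontal distance (um) from the nearest track edge
    d_cols = (np.abs(c - tcol) - half_w) * pixel_size
    signal_row = gt.background * (
        1.0 + gt.amplitude * np.exp(-np.maximum(d_cols, 0.0) / gt.decay_um)
    )
    img = np.tile(signal_row, (rows, 1))
    in_track = np.abs(c - tcol) <= half_w
    img[:trow, in_track] = 0.02 * gt.background  # explanted-track void
    img = img + rng.normal(0.0, gt.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    image = FluorescenceImage(
        data=img, pixel_size=pixel_size, channel=channel, material=material,
        tip_center=(trow, tcol),
    )
    record = {
        "background": gt.background, "amplitude": gt.amplitude,
        "decay_um": gt.decay_um, "noise_sd": gt.noise_sd,
        "track_width_um": gt.track_width_um, "seed": gt.seed,
        "tip_center": (trow, tcol), "pixel_size": pixel_size,
    }
    return image, record


def make_group_study(
    amplitudes: dict[str, float] | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    channel: str = "GFAP",
    noise_sd: float = 100.0,
    decay_um: float = 120.0,
) -> tuple[list[FluorescenceImage], list[dict]]:
    """Synthetic 4-week group experiment: n images per material.

    Per-image seeds derive from ``seed`` via a SeedSequence, so the study
    is reproducible image-by-image.  Returns (images, ground-truth records).
    """
    if amplitudes is None:
        amplitudes = dict(GROUP_AMPLITUDES)
    if len(amplitudes) < 2 or n_replicates < 3:
        raise ValueError("need >= 2 materials and >= 3 replicates")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(amplitudes) * n_replicates) % (2**31)
    images, records = [], []
    k = 0
    for material in amplitudes:
        for _ in range(n_replicates):
            gt = IHCGroundTruth(
                amplitude=amplitudes[material], noise_sd=noise_sd,
                decay_um=decay_um, seed=int(child_seeds[k]),
            )
            img, rec = generate_ihc_image(gt, channel=channel,
                                          material=material)
            rec["material"] = material
            images.append(img)
            records.append(rec)
            k += 1
    return images, records


# ---------------------------------------------------------------------------
# solver fixtures


def box_mesh(nx: int, ny: int, nz: int,
             lengths=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
             region: int = 0, jitter: float = 0.0, seed: int = 0) -> geo.Mesh:
    """Structured box of hexahedra (mm); optional interior-node jitter."""
    xs = np.linspace(origin[0], origin[0] + lengths[0], nx + 1)
    ys = np.linspace(origin[1], origin[1] + lengths[1], ny + 1)
    zs = np.linspace(origin[2], origin[2] + lengths[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        interior = (
            (nodes[:, 0] > xs[0]) & (nodes[:, 0] < xs[-1])
            & (nodes[:, 1] > ys[0]) & (nodes[:, 1] < ys[-1])
            & (nodes[:, 2] > zs[0]) & (nodes[:, 2] < zs[-1])
        )
        h = min(lengths[0] / nx, lengths[1] / ny, lengths[2] / nz)
        nodes[interior] += rng.uniform(-jitter * h, jitter * h,
                                       size=(interior.sum(), 3))

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                     nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                     nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                )
    hexes = np.array(hexes, dtype=int)
    empty = np.zeros((0, 4), dtype=int)
    return geo.Mesh(
        nodes=nodes, hexes=hexes,
        region=np.full(len(hexes), region, dtype=np.int8),
        facet_sets={"probe_top": empty},
        contact_tissue_nodes=np.zeros(0, dtype=int),
        contact_probe_nodes=np.zeros(0, dtype=int),
        contact_normals=np.zeros((0, 3)), contact_areas=np.zeros(0),
        bulk_size=max(lengths) / max(nx, ny, nz),
        contact_size=min(lengths) / max(nx, ny, nz),
    )


def solver_fixture(kind: str) -> dict:
    """Self-contained verification fixtures with closed-form references.

    Kinds: single_element_uniaxial, patch_test, friction_block,
    two_material_bar.  Each returns a dict with the mesh, materials,
    Dirichlet data (as node-id/component selectors) and a ``reference``
    entry describing the analytic solution.
    """
    if kind == "single_element_uniaxial":
        mesh = box_mesh(1, 1, 1)
        mu0 = mat.material_lookup("brain_tissue").initial_shear_modulus
        tissue = mat.material_lookup(
            "brain_tissue", volumetric_penalty=1e7 * mu0
        )
        return {
            "mesh": mesh,
            "tissue": tissue,
            "reference": lambda lam: mat.ogden_uniaxial_nominal_stress(
                lam, tissue
            ),
            "note": "prescribe z-stretch, lateral faces free; nominal "
            "stress = z-reaction / reference area; penalty 1e7*mu0 puts "
            "the model within ~1e-7 of the incompressible limit",
        }
    if kind == "patch_test":
        mesh = box_mesh(2, 2, 2, jitter=0.15, seed=42)
        hydrogel = mat.material_lookup("hydrogel")
        grad = np.array(
            [[1e-3, 4e-4, -2e-4], [4e-4, -5e-4, 3e-4], [-2e-4, 3e-4, 8e-4]]
        )
        return {
            "mesh": mesh,
            "tissue": hydrogel,
            "displacement_gradient": grad,
            "reference": "u = grad @ X on the boundary reproduces the "
            "uniform strain field exactly at every interior node",
        }
    if kind == "friction_block":
        # soft elastic block resting on a fixed rigid slab through four
        # node-to-node contact pairs; Coulomb slip when F_t = cof * F_n
        block = box_mesh(1, 1, 1, region=0)
        slab = box_mesh(1, 1, 1, origin=(0.0, 0.0, -1.0), region=1)
        nodes = np.vstack([block.nodes, slab.nodes])
        hexes = np.vstack([block.hexes, slab.hexes + len(block.nodes)])
        regionv = np.concatenate([block.region, slab.region])
        bot = np.where(np.abs(block.nodes[:, 2]) < 1e-12)[0]
        top_slab = np.where(np.abs(slab.nodes[:, 2]) < 1e-12)[0]
        # match coincident pairs by (x, y)
        order_b = np.lexsort(block.nodes[bot, :2].T)
        order_s = np.lexsort(slab.nodes[top_slab, :2].T)
        ct = bot[order_b]
        cp = top_slab[order_s] + len(block.nodes)
        empty = np.zeros((0, 4), dtype=int)
        mesh = geo.Mesh(
            nodes=nodes, hexes=hexes, region=regionv,
            facet_sets={"probe_top": empty},
            contact_tissue_nodes=ct, contact_probe_nodes=cp,
            contact_normals=np.tile([0.0, 0.0, 1.0], (len(ct), 1)),
            contact_areas=np.full(len(ct), 0.25),
            bulk_size=1.0, contact_size=1.0,
        )
        soft = mat.LinearElasticParameters(1e4, 0.3, 1000.0)
        stiff = mat.LinearElasticParameters(1e8, 0.3, 1000.0)
        return {
            "mesh": mesh,
            "tissue": soft,
            "probe": stiff,
            "reference": "slip onset when tangential force equals "
            "cof * normal force (Coulomb law)",
        }
    if kind == "two_material_bar":
        bar1 = box_mesh(1, 1, 1, lengths=(1.0, 0.5, 0.5))
        bar2 = box_mesh(1, 1, 1, lengths=(1.0, 0.5, 0.5), origin=(1.0, 0, 0),
                        region=1)
        # share the interface nodes
        nodes = np.vstack([bar1.nodes, bar2.nodes])
        key = [tuple(np.round(p, 12)) for p in nodes]
        uniq = {}
        remap = np.empty(len(nodes), dtype=int)
        unique_nodes = []
        for i, k in enumerate(key):
            if k not in uniq:
                uniq[k] = len(unique_nodes)
                unique_nodes.append(nodes[i])
            remap[i] = uniq[k]
        hexes = np.vstack([remap[bar1.hexes], remap[bar2.hexes + len(bar1.nodes)]])
        empty = np.zeros((0, 4), dtype=int)
        mesh = geo.Mesh(
            nodes=np.array(unique_nodes), hexes=hexes,
            region=np.array([0, 1], dtype=np.int8),
            facet_sets={"probe_top": empty},
            contact_tissue_nodes=np.zeros(0, dtype=int),
            contact_probe_nodes=np.zeros(0, dtype=int),
            contact_normals=np.zeros((0, 3)), contact_areas=np.zeros(0),
            bulk_size=1.0, contact_size=0.5,
        )
        e1, e2 = 2e4, 8e4
        m1 = mat.LinearElasticParameters(e1, 0.0, 1000.0)
        m2 = mat.LinearElasticParameters(e2, 0.0, 1000.0)
        return {
            "mesh": mesh,
            "tissue": m1,
            "probe": m2,
            "reference": {
                # series springs: interface displacement fraction of the
                # total elongation (small strain, nu = 0)
                "interface_fraction": (1.0 / e1) / (1.0 / e1 + 1.0 / e2),
            },
        }
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# scenario sweeps


def study_scenarios(preset: str = "reduced") -> list[fes.Scenario]:
    """The full simulation sweep: 13 unique scenarios.

    Material sweep: steel / silica / PC / hydrogel, circular section,
    COF 0.3.  COF sweep: hydrogel at COF 0.1, 0.5, 0.7, 0.9 (0.3 is the
    baseline already present).  Geometry sweep at fixed area 0.04*pi mm^2:
    hydrogel with ellipse 1:2, 1:3, square, rounded square, octagon
    (ellipse 1:1 is the baseline).
    """
    scenarios = [
        fes.Scenario(name=f"material_{m}", material=m, preset=preset)
        for m in ("steel", "silica", "PC", "hydrogel")
    ]
    scenarios += [
        fes.Scenario(name=f"cof_{c}", material="hydrogel", cof=c,
                     preset=preset)
        for c in (0.1, 0.5, 0.7, 0.9)
    ]
    scenarios += [
        fes.Scenario(name=f"ellipse_1to{r}", material="hydrogel",
                     section_ratio=r, preset=preset)
        for r in (2, 3)
    ]
    scenarios += [
        fes.Scenario(name=f"shape_{k}", material="hydrogel", section_kind=k,
                     preset=preset)
        for k in ("square", "rounded_square", "octagon")
    ]
    return scenarios
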