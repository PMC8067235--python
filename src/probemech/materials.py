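"""Constitutive models for the probe-tissue system.

Brain tissue is modeled as an isotropic, homogeneous, nearly incompressible
Ogden hyperelastic solid.  The strain energy per unit reference volume is

    W = sum_i (mu_i / alpha_i) (lbar1^a_i + lbar2^a_i + lbar3^a_i - 3)
        + kappa/2 (J - 1)^2,

where lbar_l = J^(-1/3) lambda_l are the deviatoric (isochoric) principal
stretches, J = lambda1 lambda2 lambda3 is the volume ratio and kappa is a
volumetric penalty enforcing near-incompressibility.  The first-order set
(mu1 = 8.1 Pa, alpha1 = 15.7) represents hippocampal (CA3SR) tissue of the
adult rodent brain; the initial shear modulus is mu0 = sum mu_i alpha_i / 2
(~63.6 Pa), consistent with the extreme softness of hippocampal tissue.

Probe materials (steel, silica, polycarbonate, hydrogel) are linearly
elastic; their constants are shipped in ``data/materials.yaml`` (SI units).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "InvalidKinematicsError",
    "MaterialLookupError",
    "OgdenParameters",
    "LinearElasticParameters",
    "KinematicState",
    "deviatoric_stretches",
    "ogden_energy",
    "ogden_uniaxial_nominal_stress",
    "ogden_principal_kirchhoff",
    "ogden_principal_moduli",
    "material_lookup",
    "available_materials",
]


class InvalidKinematicsError(ValueError):
    """Raised for physically inadmissible kinematic input (e.g. stretch <= 0)."""


class MaterialLookupError(KeyError):
    """Raised when a material name is not in the library."""


@dataclass(frozen=True)
class OgdenParameters:
    """Parameters of an N-term Ogden model with a quadratic volumetric penalty.

    mu : shear-like moduli, Pa (one per term)
    alpha : dimensionless exponents (one per term, nonzero)
    volumetric_penalty : bulk-like penalty kappa, Pa.  Defaults to
        1e5 * mu0, which keeps |J - 1| below ~1e-5 at the stress levels of
        the micromotion problem.  Must be >= 1e4 * mu0 so that the model is
        effectively incompressible.
    density : kg/m^3; brain tissue density is not a measured input of the
        model and only matters when inertia is switched on.
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    volumetric_penalty: float | None = None
    density: float = 1040.0

    def __post_init__(self):
        mu = tuple(float(m) for m in np.atleast_1d(self.mu))
        alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        if len(mu) < 1 or len(mu) != len(alpha):
            raise ValueError("need N >= 1 terms with matching mu/alpha")
        if any(a == 0.0 for a in alpha):
            raise ValueError("alpha_i must be nonzero")
        mu0 = self.initial_shear_modulus
        if mu0 <= 0.0:
            raise ValueError(f"initial shear modulus mu0 = {mu0} must be positive")
        if self.volumetric_penalty is None:
            object.__setattr__(self, "volumetric_penalty", 1e5 * mu0)
        if self.volumetric_penalty < 1e4 * mu0:
            raise ValueError(
                "volumetric_penalty must be >= 1e4 * mu0 for near-incompressibility"
            )
        if self.density <= 0.0:
            raise ValueError("density must be positive")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def initial_shear_modulus(self) -> float:
        """mu0 = sum_i mu_i alpha_i / 2 (ground-state shear modulus, Pa)."""
        return 0.5 * sum(m * a for m, a in zip(self.mu, self.alpha))


@dataclass(frozen=True)
class LinearElasticParameters:
    """Isotropic linear elasticity: E (Pa), nu (-), rho (kg/m^3)."""

    youngs_modulus: float
    poissons_ratio: float
    density: float

    def __post_init__(self):
        if self.youngs_modulus <= 0.0:
            raise ValueError("youngs_modulus must be positive")
        if not (0.0 <= self.poissons_ratio < 0.5):
            raise ValueError("poissons_ratio must be in [0, 0.5)")
        if self.density <= 0.0:
            raise ValueError("density must be positive")

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poissons_ratio))

    @property
    def lame_lambda(self) -> float:
        e, nu = self.youngs_modulus, self.poissons_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class KinematicState:
    """Principal stretches, volume ratio and deviatoric stretches."""

    stretches: tuple[float, float, float]
    J: float
    deviatoric: tuple[float, float, float]


def deviatoric_stretches(l1: float, l2: float, l3: float) -> KinematicState:
    """Split principal stretches into volume ratio J and deviatoric part.

    J = l1 l2 l3,  lbar_l = J^(-1/3) l_l, so that lbar1 lbar2 lbar3 = 1.
    """
    lam = np.asarray([l1, l2, l3], dtype=float)
    if not np.all(lam > 0.0):
        raise InvalidKinematicsError(f"principal stretches must be positive, got {lam}")
    J = float(np.prod(lam))
    dev = lam * J ** (-1.0 / 3.0)
    return KinematicState(stretches=tuple(lam), J=J, deviatoric=tuple(dev))


def ogden_energy(state: KinematicState, p: OgdenParameters) -> float:
    """Strain energy density (Pa) of the penalized Ogden model."""
    dev = np.asarray(state.deviatoric, dtype=float)
    w = 0.0
    for m, a in zip(p.mu, p.alpha):
        w += (m / a) * (np.sum(dev**a) - 3.0)
    w += 0.5 * p.volumetric_penalty * (state.J - 1.0) ** 2
    return float(w)


def ogden_uniaxial_nominal_stress(lam, p: OgdenParameters):
    """Nominal (first Piola-Kirchhoff) stress for incompressible uniaxial tension.

    Lateral stretches are lam^(-1/2); the lateral-traction-free condition
    fixes the pressure, giving

        P(lam) = sum_i mu_i (lam^(a_i - 1) - lam^(-a_i/2 - 1)).

    The analytic oracle for single-element solver verification.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidKinematicsError("stretch must be positive")
    P = np.zeros_like(lam)
    for m, a in zip(p.mu, p.alpha):
        P = P + m * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return P if P.ndim else float(P)


def ogden_principal_kirchhoff(lam, p: OgdenParameters, *, iso=True, vol=True):
    """Principal Kirchhoff stresses tau_a of the penalized Ogden model.

    Parameters
    ----------
    lam : (..., 3) array of principal stretches.
    iso, vol : include the isochoric / volumetric contribution.  The solver
        integrates the two parts on different quadrature rules (selective
        reduced integration), hence the switches.

    Returns
    -------
    tau : (..., 3) array, tau_a = lam_a * dW/dlam_a (no sum).
    """
    lam = np.asarray(lam, dtype=float)
    J = np.prod(lam, axis=-1, keepdims=True)
    tau = np.zeros_like(lam)
    if iso:
        lbar = lam * J ** (-1.0 / 3.0)
        for m, a in zip(p.mu, p.alpha):
            pw = lbar**a
            tau += m * (pw - np.mean(pw, axis=-1, keepdims=True))
    if vol:
        tau += p.volumetric_penalty * J * (J - 1.0)
    return tau


def ogden_principal_moduli(lam, p: OgdenParameters, *, iso=True, vol=True):
    """d tau_a / d eps_b (eps = log stretch): the principal tangent moduli.

    Returns (..., 3, 3); symmetric.  Together with ``ogden_principal_kirchhoff``
    this fully determines the material tangent of an isotropic hyperelastic
    solid in the principal frame.
    """
    lam = np.asarray(lam, dtype=float)
    J = np.prod(lam, axis=-1, keepdims=True)
    shape = lam.shape[:-1]
    g = np.zeros(shape + (3, 3), dtype=float)
    eye = np.eye(3)
    if iso:
        lbar = lam * J ** (-1.0 / 3.0)
        for m, a in zip(p.mu, p.alpha):
            pw = lbar**a  # (..., 3)
            s = np.sum(pw, axis=-1)[..., None, None]
            # d tau_a / d eps_b = mu a [pw_a d_ab - pw_a/3 - pw_b/3 + s/9]
            g += m * a * (
                pw[..., :, None] * eye
                - pw[..., :, None] / 3.0
                - pw[..., None, :] / 3.0
                + s / 9.0
            )
    if vol:
        Jv = J[..., None]
        g += p.volumetric_penalty * (2.0 * Jv**2 - Jv) * np.ones((3, 3))
    return g


# ---------------------------------------------------------------------------
# material library

_LIB_CACHE: dict | None = None


def _load_library() -> dict:
    global _LIB_CACHE
    if _LIB_CACHE is None:
        text = resources.files("probemech.data").joinpath("materials.yaml").read_text()
        _LIB_CACHE = yaml.safe_load(text)
    return _LIB_CACHE


def available_materials() -> list[str]:
    return sorted(_load_library())


def material_lookup(name: str, **overrides):
    """Return the library entry for ``name`` as a parameter object.

    Probe materials map to :class:`LinearElasticParameters`; ``brain_tissue``
    maps to :class:`OgdenParameters`.  Keyword overrides replace library
    fields (e.g. ``volumetric_penalty=...`` for the tissue).
    """
    lib = _load_library()
    if name not in lib:
        raise MaterialLookupError(
            f"unknown material {name!r}; valid names: {', '.join(sorted(lib))}"
        )
    entry = dict(lib[name])
    model = entry.pop("model")
    entry.update(overrides)
    if model == "ogden":
        entry["mu"] = tuple(entry["mu"])
        entry["alpha"] = tuple(entry["alpha"])
        return OgdenParameters(**entry)
    if model == "linear_elastic":
        return LinearElasticParameters(**entry)
    raise MaterialLookupError(f"unknown model kind {model!r} for {name!r}")
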