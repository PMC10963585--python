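"""Constitutive laws of the tri-phasic porous lobule mixture.

The homogenized continuum superposes three immiscible phases -- solid liver
tissue (S), fat tissue (T) and blood (F) -- with volume fractions summing to
one (saturation), plus miscible solutes: glycogen in the solid, glucose,
lactate, free fatty acids (FFA) and oxygen in the blood.  The laws collected
here are the thermodynamically admissible restrictions:

* effective Neo-Hookean solid+fat stress with the pore-pressure (Lagrange
  multiplier) contribution,
* fluid partial stress with osmotic pressure Pi = c R theta,
* ideal-dilute chemical potential mu = mu0 + R theta ln(c/c_ref) and its
  exact inverse,
* transverse-isotropic Darcy permeability, degraded as fat crowds the pores,
* Darcy (blood) and solute seepage velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

G_GRAVITY = 9.81  # m/s^2, converts the Darcy coefficient [m/s] to mobility


class ParameterError(ValueError):
    """Inconsistent or out-of-range material/kinetic parameter."""


class KinematicsError(ValueError):
    """Non-physical local kinematics (e.g. non-positive Jacobian)."""


@dataclass
class MaterialParams:
    """Continuum constants of a liver lobule.

    Defaults are the literature values for human lobule tissue: initial
    volume fractions 0.8 / 0.02 / 0.18 (solid / fat / blood), Lame pairs
    lam = 3e4 Pa and mu = 4e4 Pa for both tissue phases, temperature 280 K,
    gas constant 8.3144 J/(mol K) and Darcy coefficient 4.5e-10 m/s.
    """

    n0_S: float = 0.8
    n0_T: float = 0.02
    n0_F: float = 0.18
    lam_S: float = 3.0e4      # Pa
    mu_S: float = 4.0e4       # Pa
    lam_T: float = 3.0e4      # Pa
    mu_T: float = 4.0e4       # Pa
    theta: float = 280.0      # K
    R: float = 8.3144         # J/(mol K)
    k_D: float = 4.5e-10      # m/s
    rho_SR: float = 1070.0    # kg/m^3
    rho_TR: float = 920.0     # kg/m^3
    rho_FR: float = 1050.0    # kg/m^3
    aniso_weight: float = 0.5  # omega in [0, 1)
    perm_exponent: float = 1.0  # m in (n_F/n0_F)^m

    def __post_init__(self):
        if abs(self.n0_S + self.n0_T + self.n0_F - 1.0) > 1e-12:
            raise ParameterError(
                f"initial volume fractions must sum to 1, got "
                f"{self.n0_S + self.n0_T + self.n0_F!r}")
        for name in ("lam_S", "mu_S", "lam_T", "mu_T", "theta", "k_D",
                     "rho_SR", "rho_TR", "rho_FR", "R"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not 0.0 <= self.aniso_weight < 1.0:
            raise ParameterError("aniso_weight must lie in [0, 1)")

    @property
    def darcy_mobility(self) -> float:
        """Isotropic hydraulic mobility k_D / (rho_FR g) [m^2/(Pa s)]."""
        return self.k_D / (self.rho_FR * G_GRAVITY)

    def replace(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SoluteSpec:
    """One miscible component: carried by the solid (S) or the fluid (F)."""

    name: str
    carrier: str           # "S" or "F"
    M_mol: float           # kg/mol
    diffusivity: float     # m^2/s, sets the diffusive drag gamma_FbS
    c_ref: float = 1.0     # mol/m^3
    mu0: float = 0.0       # J/mol
    advect_factor: float = 1.0  # fraction of the blood velocity carried

    def __post_init__(self):
        if self.carrier not in ("S", "F"):
            raise ParameterError("carrier must be 'S' or 'F'")
        if self.M_mol <= 0 or self.c_ref <= 0:
            raise ParameterError("M_mol and c_ref must be positive")
        if self.diffusivity <= 0 and self.carrier == "F":
            raise ParameterError("fluid solutes need a positive diffusivity")


def default_solutes() -> dict[str, SoluteSpec]:
    """The penta-substance set: glycogen bound to the solid, glucose,
    lactate, FFA and oxygen dissolved in the blood.  Glucose/lactate
    kinetics are stubbed off by default (they are transportable only)."""
    return {
        "Gy": SoluteSpec("Gy", "S", M_mol=0.162, diffusivity=0.0),
        "Gu": SoluteSpec("Gu", "F", M_mol=0.18016, diffusivity=6.0e-10),
        "Lc": SoluteSpec("Lc", "F", M_mol=0.09008, diffusivity=1.0e-9),
        "FFA": SoluteSpec("FFA", "F", M_mol=0.2825, diffusivity=2.0e-11),
        "Ox": SoluteSpec("Ox", "F", M_mol=0.032, diffusivity=1.0e-10),
    }


@dataclass
class LocalKinematics:
    """Deformation state at one evaluation point (plane-strain 2D)."""

    F_S: np.ndarray = field(default_factory=lambda: np.eye(2))
    n_S: float = 0.8
    n_T: float = 0.02
    n_F: float = 0.18
    lam: float = 0.0  # Lagrange multiplier == pore pressure p^FR [Pa]

    @property
    def J_S(self) -> float:
        return float(np.linalg.det(self.F_S))

    @property
    def K_S(self) -> np.ndarray:
        """Almansi-type strain 0.5 (B_S - I); linear elasticity at small
        strain, which is the regime of the quasi-static lobule problem."""
        B = self.F_S @ self.F_S.T
        return 0.5 * (B - np.eye(2))

    def check(self):
        if self.J_S <= 0:
            raise KinematicsError(f"non-positive Jacobian J_S={self.J_S}")
        if abs(self.n_S + self.n_T + self.n_F - 1.0) > 1e-8:
            raise KinematicsError("saturation violated beyond 1e-8")


# ---------------------------------------------------------------------------
# stresses
# ---------------------------------------------------------------------------

def solid_fat_stress(kin: LocalKinematics, p: MaterialParams) -> np.ndarray:
    """Combined partial Cauchy stress of solid and fat tissue [Pa].

    (rho^S/rho^S_0S)(lam_S ln J I + 2 mu_S K_S)
      + (rho^T/rho^T_0S)(lam_T ln J I + 2 mu_T K_S) - lam (n_S + n_T) I.
    The partial-density ratios reduce to (n_alpha J / n0_alpha) for
    incompressible constituents.
    """
    kin.check()
    J = kin.J_S
    K = kin.K_S
    I2 = np.eye(2)
    lnJ = np.log(J)
    wS = kin.n_S * J / p.n0_S
    wT = kin.n_T * J / p.n0_T
    sig = wS * (p.lam_S * lnJ * I2 + 2.0 * p.mu_S * K)
    sig += wT * (p.lam_T * lnJ * I2 + 2.0 * p.mu_T * K)
    sig -= kin.lam * (kin.n_S + kin.n_T) * I2
    return 0.5 * (sig + sig.T)


def fluid_stress(n_F: float, lam: float, Pi: float) -> np.ndarray:
    """Fluid partial stress  T^F = -n_F (lam + Pi) I  [Pa]."""
    if not 0.0 < n_F < 1.0:
        raise ParameterError(f"n_F must lie in (0, 1), got {n_F}")
    return -n_F * (lam + Pi) * np.eye(2)


def osmotic_pressure(c, p: MaterialParams):
    """Osmotic pressure Pi = c R theta [Pa] of a dilute solute."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ParameterError("negative concentration reached osmotic_pressure "
                             "(upstream inversion fault)")
    return c * p.R * p.theta


# ---------------------------------------------------------------------------
# chemical potential <-> concentration
# ---------------------------------------------------------------------------

C_MIN_FLOOR = 1e-9  # mol/m^3, keeps the logarithm well-defined

_floor_activations = {"count": 0}


def chemical_potential_floor_count() -> int:
    """How often concentrations were floored at C_MIN_FLOOR so far."""
    return _floor_activations["count"]


def chemical_potential(c, s: SoluteSpec, p: MaterialParams, c_min: float = C_MIN_FLOOR):
    """mu = mu0 + R theta ln(c / c_ref) [J/mol]; c is floored at c_min."""
    c = np.asarray(c, dtype=float)
    if np.any(c < c_min):
        _floor_activations["count"] += int(np.sum(c < c_min))
        c = np.maximum(c, c_min)
    return s.mu0 + p.R * p.theta * np.log(c / s.c_ref)


def concentration_from_potential(mu, s: SoluteSpec, p: MaterialParams):
    """Exact inverse of :func:`chemical_potential`."""
    mu = np.asarray(mu, dtype=float)
    return s.c_ref * np.exp((mu - s.mu0) / (p.R * p.theta))


# ---------------------------------------------------------------------------
# permeability and seepage
# ---------------------------------------------------------------------------

def permeability_scalar(n_F, p: MaterialParams):
    """Effective isotropic mobility k_eff(n_F) [m^2/(Pa s)].

    k_eff = k_D/(rho_FR g) * (n_F/n0_F)^m: fat growth shrinks the blood
    fraction and throttles perfusion, nearly linearly for m = 1.
    """
    n_F = np.asarray(n_F, dtype=float)
    if np.any(n_F <= 0) or np.any(n_F >= 1):
        raise ParameterError("n_F must lie in (0, 1)")
    return p.darcy_mobility * (n_F / p.n0_F) ** p.perm_exponent


def permeability_tensor(n_F, direction, p: MaterialParams):
    """Transverse-isotropic permeability K_F [m^2/(Pa s)].

    K_F = k_eff(n_F) [ (1-omega) I + omega d (x) d ] with the unit vector d
    pointing toward the central vein.  SPD for omega < 1.  Broadcasts over
    leading axes of *n_F* and *direction*.
    """
    if not 0.0 <= p.aniso_weight < 1.0:
        raise ParameterError("aniso_weight must lie in [0, 1)")
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d, axis=-1)
    if np.any(np.abs(nrm - 1.0) > 1e-9):
        raise ParameterError("direction vectors must be unit length")
    k = np.asarray(permeability_scalar(n_F, p))
    I2 = np.eye(2)
    dd = d[..., :, None] * d[..., None, :]
    return k[..., None, None] * ((1.0 - p.aniso_weight) * I2 + p.aniso_weight * dd)


def seepage_velocity(K_F, grad_lam):
    """Filter velocity n_F w_FS = K_F (-grad lam) [m/s]; broadcasts."""
    g = np.asarray(grad_lam, dtype=float)
    return -np.einsum("...ij,...j->...i", np.asarray(K_F, dtype=float), g)


def darcy_dissipation(K_F, grad_lam):
    """Pointwise Darcy entropy production (-grad lam) . K_F (-grad lam) >= 0."""
    g = -np.asarray(grad_lam, dtype=float)
    return np.einsum("...i,...ij,...j->...", g, np.asarray(K_F, dtype=float), g)


def solute_drag(c, n_F, s: SoluteSpec, p: MaterialParams):
    """Diffusive drag gamma_FbS chosen so the diffusive solute flux is
    -n_F D grad c (Fick's law with diffusivity D = s.diffusivity)."""
    if s.diffusivity <= 0:
        raise ParameterError(f"solute {s.name!r} has no positive diffusivity "
                             "(zero drag is inadmissible)")
    c = np.maximum(np.asarray(c, dtype=float), C_MIN_FLOOR)
    return np.asarray(n_F) * c * p.R * p.theta / s.diffusivity


def solute_seepage(n_F, grad_Pi, w_FS, c, s: SoluteSpec, p: MaterialParams):
    """Solute seepage velocity w_FbS [m/s].

    Diffusion runs down the osmotic-pressure (hence concentration) gradient;
    advection carries the solute with the blood at advect_factor * w_FS.
    Broadcasts over leading axes.
    """
    gamma = solute_drag(c, n_F, s, p)
    if np.any(gamma <= 0):
        raise ParameterError("solute drag must be strictly positive")
    nf = np.asarray(n_F, dtype=float)
    diff = -(nf / gamma)[..., None] * np.asarray(grad_Pi, dtype=float)
    return diff + s.advect_factor * np.asarray(w_FS, dtype=float)
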