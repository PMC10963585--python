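"""Hepatocyte fat-metabolism ODEs, solved per quadrature point.

Three state variables per material point: intracellular free-fatty-acid
concentration, intracellular oxygen concentration (both mmol/l, which is
numerically identical to mol/m^3) and the triglyceride (TG) store expressed
as a partial-density contribution [kg/m^3].  Reactions:

* uptake of plasma FFA and oxygen -- Michaelis-Menten in the local plasma
  concentrations delivered by the lobule-scale transport model,
* TG synthesis (esterification)     v_syn = k_syn * c_FFA_int,
* mitochondrial beta-oxidation      v_oxy = k_oxy * c_FFA_int * sat(c_Ox_int),
  consuming FFA and oxygen, saturable in oxygen,
* background oxidative load         v_deg = k_deg * c_Ox_int,
* TG export (VLDL secretion)        first-order decay k_exp of the store.

The competition between synthesis and oxygen-dependent oxidation is what
turns the lobule-scale oxygen gradient into a zonated fat pattern: hypoxic
pericentral tissue oxidizes little and esterifies much.

The rate constants are not literature transcriptions; they are calibrated
once (scripts/calibrate_kinetics.py) so that the standard inflow conditions
(FFA 3 mmol/l or 0.2 mmol/l, oxygen 0.091 mmol/l) reproduce pericentral and
periportal steatosis respectively on the reference lobule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class CellModelError(ValueError):
    pass


@dataclass
class KineticParams:
    """Rate constants of the hepatocyte fat-metabolism model.

    Units: vmax_* in mmol/l/s, KM_* in mmol/l, k_* in 1/s, rho_conv in
    kg/mol (mass of stored TG per mole of esterified FFA; calibrated,
    time-compressed -- see docs/methods.md).
    """

    vmax_FFA: float = 1.05e-4
    KM_FFA: float = 0.35
    vmax_Ox: float = 2.5e-4
    KM_Ox: float = 0.04
    k_syn: float = 2.0e-3
    k_oxy: float = 2.0e-2
    KM_oxy: float = 0.03
    k_deg: float = 5.0e-3
    k_exp: float = 1.0e-4
    rho_conv: float = 900.0

    def __post_init__(self):
        for name in ("vmax_FFA", "vmax_Ox", "k_syn", "k_oxy", "k_deg",
                     "k_exp", "rho_conv"):
            if getattr(self, name) < 0:
                raise CellModelError(f"{name} must be non-negative")
        for name in ("KM_FFA", "KM_Ox", "KM_oxy"):
            if getattr(self, name) <= 0:
                raise CellModelError(f"{name} must be strictly positive")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)

    def zero_kinetics(self) -> "KineticParams":
        """All rates off; used for the no-growth limit."""
        return self.replace(vmax_FFA=0.0, vmax_Ox=0.0, k_syn=0.0,
                            k_oxy=0.0, k_deg=0.0, k_exp=0.0)


@dataclass
class CellState:
    """State of the hepatocyte model at one quadrature point."""

    c_FFA_int: float = 0.0  # mmol/l
    c_Ox_int: float = 0.0   # mmol/l
    tg: float = 0.0         # kg/m^3 (partial TG density contribution)

    def as_array(self) -> np.ndarray:
        return np.array([self.c_FFA_int, self.c_Ox_int, self.tg])


def michaelis_menten(c, vmax, KM):
    """Saturable rate vmax * c / (KM + c); bounded by vmax."""
    c = np.asarray(c, dtype=float)
    if KM <= 0:
        raise CellModelError("KM must be strictly positive")
    if np.any(c < 0):
        raise CellModelError("negative concentration (transport fault upstream)")
    return vmax * c / (KM + c)


def _ox_sat(o, k: KineticParams):
    return o / (k.KM_oxy + o)


def cell_rhs(s: CellState, plasma_FFA: float, plasma_Ox: float, k: KineticParams):
    """Right-hand side of the cell ODEs.

    Returns (dc_FFA_int/dt, dc_Ox_int/dt, rho_hat_T, uptake_FFA, uptake_Ox);
    the uptake rates are reported for the plasma-side sinks of the
    lobule-scale solute balances.  rho_hat_T = rho_conv*v_syn - k_exp*tg is
    the TG partial-density production [kg/m^3/s].
    """
    if min(s.c_FFA_int, s.c_Ox_int, s.tg) < 0:
        raise CellModelError("negative cell state")
    up_F = float(michaelis_menten(plasma_FFA, k.vmax_FFA, k.KM_FFA))
    up_O = float(michaelis_menten(plasma_Ox, k.vmax_Ox, k.KM_Ox))
    v_syn = k.k_syn * s.c_FFA_int
    v_oxy = k.k_oxy * s.c_FFA_int * _ox_sat(s.c_Ox_int, k)
    v_deg = k.k_deg * s.c_Ox_int
    df = up_F - v_syn - v_oxy
    do = up_O - v_oxy - v_deg
    rho_hat_T = k.rho_conv * v_syn - k.k_exp * s.tg
    return df, do, rho_hat_T, up_F, up_O


# ---------------------------------------------------------------------------
# vectorized backward-Euler integrator (the PDE-coupling workhorse)
# ---------------------------------------------------------------------------

def _be_substep(f0, o0, a_f, a_o, h, k: KineticParams, maxit=30, tol=1e-13):
    """One backward-Euler substep of the (f, o) subsystem, vectorized.

    Frozen uptake rates a_f, a_o; Newton with the analytic 2x2 Jacobian.
    """
    f, o = f0.copy(), o0.copy()
    for _ in range(maxit):
        phi = o / (k.KM_oxy + o)
        dphi = k.KM_oxy / (k.KM_oxy + o) ** 2
        F1 = f - f0 - h * (a_f - k.k_syn * f - k.k_oxy * f * phi)
        F2 = o - o0 - h * (a_o - k.k_oxy * f * phi - k.k_deg * o)
        J11 = 1.0 + h * (k.k_syn + k.k_oxy * phi)
        J12 = h * k.k_oxy * f * dphi
        J21 = h * k.k_oxy * phi
        J22 = 1.0 + h * (k.k_oxy * f * dphi + k.k_deg)
        det = J11 * J22 - J12 * J21
        df = (J22 * F1 - J12 * F2) / det
        do = (J11 * F2 - J21 * F1) / det
        f -= df
        o -= do
        if max(np.max(np.abs(df)), np.max(np.abs(do))) < tol * (1.0 + np.max(np.abs(f))):
            break
    return np.maximum(f, 0.0), np.maximum(o, 0.0)


def integrate_cells(f, o, g, uptake_F, uptake_Ox, k: KineticParams, dt: float,
                    n_sub: int = 5):
    """Advance arrays of cell states over one macro step of length *dt*.

    The plasma-side uptake rates are frozen over the step (weak macro-micro
    coupling).  Backward Euler with *n_sub* substeps; unconditionally stable
    and non-negativity preserving for these rate laws.

    Returns (f, o, g, integrals) where *integrals* holds the step-integrated
    reaction extents (mol s / m^3 scale) used by the mass audit:
    'syn', 'oxy', 'deg', 'exp_mol' (exported TG in FFA-mole equivalents).
    """
    if dt <= 0:
        raise CellModelError("dt must be positive")
    h = dt / n_sub
    syn = np.zeros_like(f)
    oxy = np.zeros_like(f)
    deg = np.zeros_like(f)
    exp_mol = np.zeros_like(f)
    for _ in range(n_sub):
        f, o = _be_substep(f, o, uptake_F, uptake_Ox, h, k)
        # TG store: linear, exact backward-Euler update
        g = (g + h * k.rho_conv * k.k_syn * f) / (1.0 + h * k.k_exp)
        syn += h * k.k_syn * f
        oxy += h * k.k_oxy * f * _ox_sat(o, k)
        deg += h * k.k_deg * o
        exp_mol += h * k.k_exp * g / k.rho_conv if k.rho_conv > 0 else 0.0
    return f, o, g, {"syn": syn, "oxy": oxy, "deg": deg, "exp_mol": exp_mol}


# ---------------------------------------------------------------------------
# single-trajectory adaptive implicit integrator
# ---------------------------------------------------------------------------

def _trap_step(y, a_f, a_o, h, k: KineticParams, maxit=30, tol=1e-14):
    """One implicit-trapezoid step of the full 3-variable system."""

    def rhs(f, o, g):
        phi = o / (k.KM_oxy + o)
        df = a_f - k.k_syn * f - k.k_oxy * f * phi
        do = a_o - k.k_oxy * f * phi - k.k_deg * o
        dg = k.rho_conv * k.k_syn * f - k.k_exp * g
        return np.array([df, do, dg])

    r0 = rhs(*y)
    z = y + h * r0  # explicit predictor
    for _ in range(maxit):
        f, o, g = z
        o_s = max(o, 0.0)
        phi = o_s / (k.KM_oxy + o_s)
        dphi = k.KM_oxy / (k.KM_oxy + o_s) ** 2
        F = z - y - 0.5 * h * (r0 + rhs(f, o_s, g))
        J = np.eye(3)
        J[0, 0] += 0.5 * h * (k.k_syn + k.k_oxy * phi)
        J[0, 1] += 0.5 * h * k.k_oxy * f * dphi
        J[1, 0] += 0.5 * h * k.k_oxy * phi
        J[1, 1] += 0.5 * h * (k.k_oxy * f * dphi + k.k_deg)
        J[2, 0] -= 0.5 * h * k.rho_conv * k.k_syn
        J[2, 2] += 0.5 * h * k.k_exp
        delta = np.linalg.solve(J, F)
        z = z - delta
        if np.max(np.abs(delta)) < tol * (1.0 + np.max(np.abs(z))):
            break
    return z


def integrate_cell(s: CellState, plasma, k: KineticParams, dt: float,
                   rtol: float = 1e-8, atol: float = 1e-12,
                   dt_min_factor: float = 1e-9) -> CellState:
    """Advance one cell state over *dt* at frozen plasma concentrations.

    Adaptive implicit trapezoidal rule (A-stable) with step-doubling error
    control and local extrapolation; non-negativity is enforced by step
    rejection, never by silently clipping mass away.
    """
    if dt <= 0:
        raise CellModelError("dt must be positive")
    plasma_FFA, plasma_Ox = plasma
    a_f = float(michaelis_menten(plasma_FFA, k.vmax_FFA, k.KM_FFA))
    a_o = float(michaelis_menten(plasma_Ox, k.vmax_Ox, k.KM_Ox))
    y = s.as_array()
    t, h = 0.0, dt / 16.0
    dt_min = dt * dt_min_factor
    while t < dt * (1.0 - 1e-14):
        h = min(h, dt - t)
        y1 = _trap_step(y, a_f, a_o, h, k)
        y2 = _trap_step(y, a_f, a_o, 0.5 * h, k)
        y2 = _trap_step(y2, a_f, a_o, 0.5 * h, k)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y2))
        err = np.max(np.abs(y2 - y1) / scale) / 3.0  # order-2 Richardson
        if (err <= 1.0) and np.all(y2 >= -atol):
            t += h
            y = np.maximum(y2 + (y2 - y1) / 3.0, 0.0)  # local extrapolation
            h *= min(4.0, 0.9 * max(err, 1e-16) ** (-1.0 / 3.0))
        else:
            h *= 0.5 if np.all(y2 >= -atol) else 0.25
            if h < dt_min:
                raise CellModelError(
                    f"cell integration failed below dt_min; state={y!r}, "
                    f"plasma=({plasma_FFA}, {plasma_Ox})")
    return CellState(c_FFA_int=float(y[0]), c_Ox_int=float(y[1]), tg=float(y[2]))


def steady_state(plasma, k: KineticParams, t_relax: float = 2.0e5):
    """(f*, o*) fixed point of the 2-variable subsystem at frozen plasma,
    found by relaxing the implicit integrator to a long horizon."""
    f = np.array([0.0])
    o = np.array([0.0])
    a_f = float(michaelis_menten(plasma[0], k.vmax_FFA, k.KM_FFA))
    a_o = float(michaelis_menten(plasma[1], k.vmax_Ox, k.KM_Ox))
    g = np.array([0.0])
    for _ in range(400):
        f, o = _be_substep(f, o, np.array([a_f]), np.array([a_o]), t_relax / 400, k)
    return float(f[0]), float(o[0])
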