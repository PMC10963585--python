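"""Scale bridging between the lobule continuum and the hepatocyte ODEs.

Macro concentrations are frozen at each quadrature point for one time step,
the cell model is integrated, and its reaction extents are lifted back as
mass-exchange terms of the mixture: a fat-phase production rho_hat_T, solute
sinks rho_hat_Fbeta for FFA and oxygen, and a compensating fluid-phase
exchange rho_hat_F that closes the mixture balance

    rho_hat_S + rho_hat_T + rho_hat_F + sum_beta rho_hat_Fbeta = 0

exactly (rho_hat_S = 0; the solid neither grows nor dissolves).  Cell rates
are per unit hepatocyte volume and scale with the tissue fraction n_S when
entering the continuum balances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import CellState, KineticParams, integrate_cell


class CouplingError(ValueError):
    pass


@dataclass
class ExchangeTerms:
    """Mass-exchange rates [kg/m^3/s]; arrays broadcast over points."""

    rho_hat_T: np.ndarray
    rho_hat_Fbeta: dict          # solute name -> array
    rho_hat_F: np.ndarray

    def closure_error(self) -> float:
        """Max |rho_hat_T + rho_hat_F + sum_beta rho_hat_Fbeta| (rho_hat_S=0)."""
        s = np.asarray(self.rho_hat_T) + np.asarray(self.rho_hat_F)
        for v in self.rho_hat_Fbeta.values():
            s = s + np.asarray(v)
        return float(np.max(np.abs(s)))


def gauss_point_exchange(cell: CellState, macro_conc: dict, n_S: float,
                         k: KineticParams, dt: float, solutes: dict):
    """Integrate one cell over *dt* at frozen plasma values and return the
    updated state plus its mass-exchange terms.

    macro_conc maps solute names to plasma concentrations (mol/m^3, which
    equals mmol/l).  Uptake sinks are scaled by the tissue fraction n_S;
    rho_hat_F enforces the closure condition exactly.
    """
    plasma = (macro_conc.get("FFA", 0.0), macro_conc.get("Ox", 0.0))
    new = integrate_cell(cell, plasma, k, dt)
    # time-averaged uptake over the step (constant at frozen plasma)
    from .cell import michaelis_menten
    up_F = float(michaelis_menten(plasma[0], k.vmax_FFA, k.KM_FFA))
    up_O = float(michaelis_menten(plasma[1], k.vmax_Ox, k.KM_Ox))
    rho_T = n_S * (new.tg - cell.tg) / dt
    rbeta = {
        "FFA": -solutes["FFA"].M_mol * n_S * up_F,
        "Ox": -solutes["Ox"].M_mol * n_S * up_O,
    }
    rho_F = -(rho_T + sum(rbeta.values()))
    ex = ExchangeTerms(rho_hat_T=np.asarray(rho_T),
                       rho_hat_Fbeta={k_: np.asarray(v) for k_, v in rbeta.items()},
                       rho_hat_F=np.asarray(rho_F))
    return new, ex


def gauss_point_exchange_arrays(f, o, tg, tg_old, uptake, n_S_cells,
                                solutes, k: KineticParams, dt: float):
    """Vectorized exchange terms for the already-integrated cell arrays."""
    rho_T = n_S_cells * (tg - tg_old) / dt
    rbeta = {name: -solutes[name].M_mol * n_S_cells * uptake[name]
             for name in uptake}
    rho_F = -(rho_T + sum(rbeta.values()))
    ex = ExchangeTerms(rho_hat_T=rho_T, rho_hat_Fbeta=rbeta, rho_hat_F=rho_F)
    return (f, o, tg), ex


def update_fat_fraction(n_T, rho_hat_T, params, dt: float, div_rate=0.0,
                        n_S=None):
    """Backward-Euler update of the fat volume fraction.

    (n_T)'_S + n_T div x'_S = rho_hat_T / rho_TR; the volumetric term is
    carried through div_rate (tr D_S).  Rejects the step if n_T leaves its
    admissible range (0, 1 - n_S).
    """
    if params.rho_TR <= 0:
        raise CouplingError("rho_TR must be positive")
    n_new = (np.asarray(n_T) + dt * np.asarray(rho_hat_T) / params.rho_TR) \
        / (1.0 + dt * np.asarray(div_rate))
    upper = 1.0 if n_S is None else 1.0 - np.asarray(n_S)
    if np.any(n_new < 0.0) or np.any(n_new >= upper):
        raise CouplingError("fat fraction left (0, 1 - n_S); step rejected")
    return n_new


def rve_average(values, weights):
    """Volume-weighted mean lifting microscale quantities to the macroscale."""
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(w < 0):
        raise CouplingError("negative quadrature weights")
    tot = w.sum()
    if tot <= 0:
        raise CouplingError("zero total weight in RVE average")
    return float((v * w).sum() / tot)


@dataclass
class MassAudit:
    """Global FFA/TG bookkeeping over a run (volume-integrated, mol).

    Identity audited: plasma-side FFA removal equals the cell-side fate,
        uptake = TG gain / rho_conv + export + oxidized + intracellular
                 storage change,
    each term accumulated through an independent accumulator.
    """

    uptake_FFA_mol: float = 0.0
    uptake_Ox_mol: float = 0.0
    syn_mol: float = 0.0
    oxy_mol: float = 0.0
    exp_mol: float = 0.0
    storage_FFA_mol: float = 0.0
    tg_gain_mol: float = 0.0
    tg_gain_kg: float = 0.0

    def accumulate(self, area, n_S_cells, uptake, integrals, tg_new, tg_old,
                   f_new, dt, k: KineticParams, f_old=None):
        w = area * n_S_cells
        self.uptake_FFA_mol += float(np.sum(w * uptake["FFA"]) * dt)
        if "Ox" in uptake:
            self.uptake_Ox_mol += float(np.sum(w * uptake["Ox"]) * dt)
        self.syn_mol += float(np.sum(w * integrals["syn"]))
        self.oxy_mol += float(np.sum(w * integrals["oxy"]))
        self.exp_mol += float(np.sum(w * integrals["exp_mol"]))
        dtg = np.asarray(tg_new) - np.asarray(tg_old)
        self.tg_gain_kg += float(np.sum(w * dtg))
        if k.rho_conv > 0:
            self.tg_gain_mol += float(np.sum(w * dtg) / k.rho_conv)
        if f_old is not None:
            self.storage_FFA_mol += float(np.sum(w * (np.asarray(f_new)
                                                      - np.asarray(f_old))))

    def ffa_balance_error(self) -> float:
        """Relative closure error of the FFA fate identity."""
        lhs = self.uptake_FFA_mol
        rhs = self.tg_gain_mol + self.exp_mol + self.oxy_mol + self.storage_FFA_mol
        scale = max(abs(lhs), abs(rhs), 1e-300)
        return abs(lhs - rhs) / scale
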