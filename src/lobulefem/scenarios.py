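"""Scenario presets, the run driver, and post-processing.

Three boundary-condition families on the single lobule / 7-lobule group:

* ``undisturbed``: inflow pressure on all portal corners and venules,
  outflow pressure at every central vein (1 mmHg = 133 Pa difference).
* ``outflow_obstruction``: the left lobule's central vein is blocked and its
  periphery held at 100 Pa; lobules are hydraulically independent, so no
  pressure gradient (hence no advection) survives in the obstructed lobule.
* ``obstruction_with_drainage``: lobules are connected, pressure is applied
  only at the portal triads (raised by 30 %), and the obstructed lobule
  drains through its neighbours' central veins.

Post-processing: porto-central zone summaries, zonation classification
(pericentral / periportal / none), and the fat-vs-perfusion relation.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constitutive as con
from . import fem, io
from .cell import KineticParams
from .mesh import (INFLOW_TAGS, TAG_OUTFLOW_CENTRAL, TAG_WALL, LobuleMesh,
                   _hex_corners, _owning_lobule_of_edges, _point_segment_distance,
                   build_lobule_group, build_single_lobule,
                   outline_inflow_nodes, porto_central_field,
                   seal_lobule_interfaces, zone_of)

PRESETS = ("undisturbed", "outflow_obstruction", "obstruction_with_drainage")


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Complete, deterministic description of one simulation run."""

    geometry: str = "single_lobule"          # or "group7"
    bc_preset: str = "undisturbed"
    p_in: float = 133.0                      # Pa (1 mmHg over outflow)
    p_out: float = 0.0                       # Pa gauge
    obstruction_pressure: float = 100.0      # Pa, preset (ii) periphery
    drainage_boost: float = 1.3              # preset (iii) inflow raise
    inflow_conc: dict = field(default_factory=lambda: {"FFA": 3.0, "Ox": 0.091})
    init_conc_frac: float = 0.03             # interior initial conc / inflow
    t_end: float = 1610.0
    dt: float = 10.0
    output_times: tuple = (0.0, 200.0, 500.0, 1000.0, 1610.0)
    circumradius: float = 5.0e-4
    target_edge_length: float | None = None
    venules: bool = True
    corner_frac: float = 0.08
    venule_frac: float = 0.15
    kinetics_on: bool = True
    displacement: bool = True
    material: con.MaterialParams = field(default_factory=con.MaterialParams)
    kinetics: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self):
        if self.geometry not in ("single_lobule", "group7"):
            raise ScenarioError(f"unknown geometry {self.geometry!r}")
        if self.bc_preset not in PRESETS:
            raise ScenarioError(f"unknown bc_preset {self.bc_preset!r}")
        if self.bc_preset != "outflow_obstruction" and not self.p_in > self.p_out:
            raise ScenarioError("perfused presets require p_in > p_out")
        if self.bc_preset != "undisturbed" and self.geometry != "group7":
            raise ScenarioError("obstruction presets are defined on the group")
        for t in self.output_times:
            if not 0.0 <= t <= self.t_end + 1e-9:
                raise ScenarioError("output_times must lie in [0, t_end]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_times"] = list(self.output_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "material" in d and isinstance(d["material"], dict):
            d["material"] = con.MaterialParams(**d["material"])
        if "kinetics" in d and isinstance(d["kinetics"], dict):
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "output_times" in d:
            d["output_times"] = tuple(d["output_times"])
        return cls(**d)

    def solver_settings(self) -> fem.SolverSettings:
        return fem.SolverSettings(dt=self.dt, t_end=self.t_end,
                                  output_times=tuple(self.output_times),
                                  displacement=self.displacement)


# ---------------------------------------------------------------------------
# geometry + boundary conditions per preset
# ---------------------------------------------------------------------------

def obstructed_lobule_index(mesh: LobuleMesh) -> int:
    """The left lobule of the group carries the obstruction."""
    return int(np.argmin(mesh.lobule_centers[:, 0]))


def _retag_central_vein(mesh: LobuleMesh, lobule: int) -> None:
    owners = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id,
                                     mesh.boundary_edges)
    sel = (owners == lobule) & (mesh.boundary_tags == TAG_OUTFLOW_CENTRAL)
    mesh.boundary_tags[sel] = TAG_WALL
    mesh.zeta = porto_central_field(mesh)


def _perimeter_nodes_of_lobule(mesh: LobuleMesh, lobule: int) -> np.ndarray:
    """Boundary nodes of one lobule lying on its hexagon outline."""
    owners = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id,
                                     mesh.boundary_edges)
    corners = _hex_corners(mesh.lobule_centers[lobule], mesh.circumradius)
    nodes = np.unique(mesh.boundary_edges[owners == lobule])
    p = mesh.vertices[nodes]
    d = np.full(len(nodes), np.inf)
    for k in range(6):
        dk, _ = _point_segment_distance(p, corners[k], corners[(k + 1) % 6])
        d = np.minimum(d, dk)
    return nodes[d < 1e-6 * mesh.circumradius]


def _portal_corner_nodes(mesh: LobuleMesh, frac: float) -> np.ndarray:
    """All mesh nodes within frac*r of any hexagon corner (incl. interior
    portal triads of the group)."""
    pts = np.vstack([_hex_corners(c, mesh.circumradius)
                     for c in mesh.lobule_centers])
    pts = np.unique(np.round(pts / (1e-9 * mesh.circumradius)), axis=0) \
        * 1e-9 * mesh.circumradius
    d = np.min(np.linalg.norm(
        mesh.vertices[:, None, :] - pts[None, :, :], axis=2), axis=1)
    return np.where(d < frac * mesh.circumradius)[0]


def build_geometry(cfg: ScenarioConfig) -> LobuleMesh:
    kw = dict(circumradius=cfg.circumradius,
              target_edge_length=cfg.target_edge_length, venules=cfg.venules,
              corner_frac=cfg.corner_frac)
    if cfg.geometry == "single_lobule":
        return build_single_lobule(**kw)
    mesh = build_lobule_group(rings=1, **kw)
    if cfg.bc_preset == "outflow_obstruction":
        mesh = seal_lobule_interfaces(mesh)
        _retag_central_vein(mesh, obstructed_lobule_index(mesh))
    elif cfg.bc_preset == "undisturbed":
        mesh = seal_lobule_interfaces(mesh)
    else:  # drainage: connected group, obstructed vein blocked
        _retag_central_vein(mesh, obstructed_lobule_index(mesh))
    return mesh


def make_boundary_conditions(cfg: ScenarioConfig,
                             mesh: LobuleMesh) -> fem.BoundaryConditions:
    def all_inflow_nodes(exclude=()):
        if cfg.geometry == "single_lobule":
            return mesh.boundary_nodes(INFLOW_TAGS)
        # sealed group: every lobule's portal corners + venules, interior
        # portal fields included
        parts = [outline_inflow_nodes(mesh, li, cfg.corner_frac,
                                      cfg.venule_frac, cfg.venules)
                 for li in range(mesh.n_lobules()) if li not in exclude]
        return np.unique(np.concatenate(parts))

    if cfg.bc_preset == "undisturbed":
        n_in = all_inflow_nodes()
        n_out = mesh.boundary_nodes(TAG_OUTFLOW_CENTRAL)
        p_nodes = [n_in, n_out]
        p_vals = [np.full(len(n_in), cfg.p_in),
                  np.full(len(n_out), cfg.p_out)]
        sol_nodes = n_in
    elif cfg.bc_preset == "outflow_obstruction":
        obs = obstructed_lobule_index(mesh)
        in_other = all_inflow_nodes(exclude=(obs,))
        out_other = mesh.boundary_nodes(TAG_OUTFLOW_CENTRAL)
        periph = _perimeter_nodes_of_lobule(mesh, obs)
        p_nodes = [in_other, out_other, periph]
        p_vals = [np.full(len(in_other), cfg.p_in),
                  np.full(len(out_other), cfg.p_out),
                  np.full(len(periph), cfg.obstruction_pressure)]
        # the obstructed lobule is fed only on its outer periphery (its
        # sealed interfaces carry no plasma); tagged inflow edges are
        # exactly the perimeter portal/venule bands
        own = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id,
                                      mesh.boundary_edges)
        obs_inflow = np.unique(mesh.boundary_edges[
            (own == obs) & np.isin(mesh.boundary_tags, list(INFLOW_TAGS))])
        sol_nodes = np.unique(np.concatenate([in_other, obs_inflow]))
    else:  # obstruction_with_drainage: portal triads only, raised pressure
        portal = _portal_corner_nodes(mesh, cfg.corner_frac)
        out_nodes = mesh.boundary_nodes(TAG_OUTFLOW_CENTRAL)
        p_nodes = [portal, out_nodes]
        p_vals = [np.full(len(portal), cfg.drainage_boost * cfg.p_in),
                  np.full(len(out_nodes), cfg.p_out)]
        sol_nodes = portal
    nodes = np.concatenate(p_nodes)
    vals = np.concatenate(p_vals)
    # later entries win on duplicates (e.g. a node both inflow and periphery)
    uniq, first = np.unique(nodes[::-1], return_index=True)
    vals = vals[::-1][first]
    return fem.BoundaryConditions(
        pressure_nodes=uniq, pressure_values=vals,
        solute_nodes={n: sol_nodes for n in cfg.inflow_conc},
        solute_values={n: np.full(len(sol_nodes), v)
                       for n, v in cfg.inflow_conc.items()},
    )


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: ScenarioConfig
    mesh: LobuleMesh
    snapshots: list                    # list[fem.MacroState]
    zone_df: pd.DataFrame              # per (t, lobule, zone) means
    audit: object
    history: fem.RunHistory
    wall_time_s: float = 0.0

    @property
    def final(self) -> fem.MacroState:
        return self.snapshots[-1]


def zone_table(mesh: LobuleMesh, snap: fem.MacroState) -> pd.DataFrame:
    """Area-weighted per-zone (and per-lobule) means of the key fields."""
    area = mesh.cell_areas()
    zeta_c = mesh.zeta[mesh.cells].mean(axis=1)
    zones = zone_of(zeta_c)
    nT_c = snap.n_T[mesh.cells].mean(axis=1)
    speed = (np.zeros(len(mesh.cells)) if snap.q_cells is None
             else np.linalg.norm(snap.q_cells, axis=1))
    conc_c = {n: v[mesh.cells].mean(axis=1) for n, v in snap.conc.items()}
    rows = []
    lobules = list(range(mesh.n_lobules())) + [-1]  # -1 = whole domain
    for lob in lobules:
        lsel = np.ones(len(mesh.cells), bool) if lob < 0 else mesh.lobule_id == lob
        for z in (1, 2, 3):
            sel = lsel & (zones == z)
            w = area[sel]
            if w.sum() <= 0:
                continue
            row = {"t": snap.t, "lobule": lob, "zone": z,
                   "mean_n_T": float(np.average(nT_c[sel], weights=w)),
                   "mean_speed": float(np.average(speed[sel], weights=w))}
            for n, cc in conc_c.items():
                row[f"mean_c_{n}"] = float(np.average(cc[sel], weights=w))
            rows.append(row)
    return pd.DataFrame(rows)


def run_scenario(cfg: ScenarioConfig, log=None) -> SimulationResult:
    """Build the geometry, apply the preset boundary conditions, advance to
    t_end, and aggregate the zone summaries."""
    t0 = time.perf_counter()
    mesh = build_geometry(cfg)
    bcs = make_boundary_conditions(cfg, mesh)
    settings = cfg.solver_settings()
    init = {n: v * cfg.init_conc_frac for n, v in cfg.inflow_conc.items()}
    solutes = con.default_solutes()
    history = fem.advance(mesh, cfg.material, cfg.kinetics, solutes, bcs,
                          settings, init, transported=tuple(cfg.inflow_conc),
                          kinetics_on=cfg.kinetics_on, log=log)
    zdf = pd.concat([zone_table(mesh, s) for s in history.snapshots],
                    ignore_index=True)
    return SimulationResult(config=cfg, mesh=mesh, snapshots=history.snapshots,
                            zone_df=zdf, audit=history.audit, history=history,
                            wall_time_s=time.perf_counter() - t0)


def stationary_perfusion(cfg: ScenarioConfig):
    """Kinetics-free stationary Darcy solution of a preset.

    Returns (mesh, p, q_cells): the rigid-skeleton pressure field and the
    per-cell filter velocity, the configuration of the microperfusion
    figures.
    """
    mesh = build_geometry(cfg)
    bcs = make_boundary_conditions(cfg, mesh)
    p, q, _ = fem.solve_stationary_darcy(
        mesh, cfg.material, bcs.pressure_nodes, bcs.pressure_values)
    return mesh, p, q


# ---------------------------------------------------------------------------
# classification and relations
# ---------------------------------------------------------------------------

def classify_zonation(result: SimulationResult, lobule: int = -1,
                      margin: float = 0.10) -> str:
    """'pericentral' if the zone-3 mean fat fraction exceeds the zone-1 mean
    by *margin* (relative), 'periportal' if reversed, else 'none'."""
    df = result.zone_df
    last_t = df["t"].max()
    sel = df[(df["t"] == last_t) & (df["lobule"] == lobule)]
    if sel.empty or result.mesh.zeta is None:
        raise ScenarioError("zone summary or porto-central field missing")
    m1 = float(sel[sel["zone"] == 1]["mean_n_T"].iloc[0])
    m3 = float(sel[sel["zone"] == 3]["mean_n_T"].iloc[0])
    if m3 > m1 * (1.0 + margin):
        return "pericentral"
    if m1 > m3 * (1.0 + margin):
        return "periportal"
    return "none"


def velocity_fat_relation(result: SimulationResult, zone: int = 2,
                          lobule: int = -1) -> dict:
    """Mid-zone fat fraction vs relative seepage-velocity magnitude.

    Returns the (n_T, v/v0) series over the snapshots together with the
    least-squares slope and R^2 of a linear fit.
    """
    df = result.zone_df
    sel = df[(df["zone"] == zone) & (df["lobule"] == lobule)].sort_values("t")
    if len(sel) < 3:
        raise ScenarioError("need at least 3 snapshots for the relation")
    n_T = sel["mean_n_T"].to_numpy()
    v = sel["mean_speed"].to_numpy()
    if v[0] <= 0:
        raise ScenarioError("zero initial velocity in the probe zone")
    rel = v / v[0]
    if np.ptp(n_T) < 1e-15:
        return {"n_T": n_T, "rel_velocity": rel, "slope": np.nan,
                "r_squared": np.nan, "constant_fat": True}
    slope, intercept = np.polyfit(n_T, rel, 1)
    fit = slope * n_T + intercept
    ss_res = float(np.sum((rel - fit) ** 2))
    ss_tot = float(np.sum((rel - rel.mean()) ** 2))
    return {"n_T": n_T, "rel_velocity": rel, "slope": float(slope),
            "intercept": float(intercept),
            "r_squared": 1.0 - ss_res / ss_tot, "constant_fat": False}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export(result: SimulationResult, outdir) -> dict:
    """Write the VTU/PVD snapshot series, zone CSV and run manifest.

    File naming is deterministic (step index, field names); the manifest
    records the config hash, library versions and wall time.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = result.mesh
    params = result.config.material
    solutes = con.default_solutes()
    series = []
    for i, snap in enumerate(result.snapshots):
        pdata = {"pressure": snap.p, "n_S": snap.n_S, "n_T": snap.n_T,
                 "n_F": snap.n_F, "zeta": mesh.zeta,
                 "displacement": snap.u[:2 * len(mesh.vertices)].reshape(-1, 2)}
        for n, v in snap.conc.items():
            pdata[f"c_{n}"] = v
            pdata[f"mu_{n}"] = snap.mu(n, solutes[n], params)
        cdata = {"lobule_id": mesh.lobule_id, "aniso_dir": mesh.aniso_dir}
        if snap.q_cells is not None:
            cdata["filter_velocity"] = snap.q_cells
        if snap.rho_hat_T_cells is not None:
            cdata["rho_hat_T"] = snap.rho_hat_T_cells
        fname = f"snapshot_{i:04d}.vtu"
        io.write_vtu(outdir / fname, mesh, pdata, cdata)
        series.append((snap.t, fname))
    io.write_pvd(outdir / "series.pvd", series)
    agg = result.zone_df[result.zone_df["lobule"] == -1]
    cols = ["t", "zone", "mean_n_T"]
    cols += [c for c in agg.columns if c.startswith("mean_c_")]
    cols += ["mean_speed"]
    agg[cols].to_csv(outdir / "zones.csv", index=False)
    manifest = io.write_manifest(outdir / "manifest.json",
                                 result.config.to_dict(), result.wall_time_s)
    return {"outdir": outdir, "n_snapshots": len(series),
            "manifest": manifest}
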