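"""Mixed finite-element machinery for the lobule-scale field equations.

Unknowns per time level (the macro DOF set): solid displacement u_S
(quadratic, Taylor-Hood pairing), pore pressure p^FR (linear), tissue and
fat volume fractions n_S, n_T (linear, pointwise evolution), and the solute
fields (linear; solved in concentration, reported also as chemical
potential).  The system is quasi-static; all first-order evolution
equations use backward Euler by default, and the macro-micro coupling is
staggered: one cell-ODE solve per quadrature point per macro step.

The individual blocks (Darcy pressure, solute transport, displacement) are
affine in their own unknown, so the generic :func:`newton_solve` converges
in a single iteration per block; nonlinearity enters through the staggered
coefficient updates (permeability from the fat fraction, uptake sinks from
the cell states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import constitutive as con
from . import coupling
from .cell import KineticParams, integrate_cells
from .mesh import LobuleMesh


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# P1 kernels
# ---------------------------------------------------------------------------

def p1_geometry(verts: np.ndarray, cells: np.ndarray):
    """Per-cell areas and constant P1 shape-function gradients (M, 3, 2)."""
    p = verts[cells]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    area = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    if np.any(area <= 0):
        raise SolverError("inverted triangles in mesh")
    # grad L_i from edge normals
    g = np.empty((len(cells), 3, 2))
    for i in range(3):
        e = p[:, (i + 2) % 3] - p[:, (i + 1) % 3]  # opposite edge
        g[:, i, 0] = -e[:, 1]
        g[:, i, 1] = e[:, 0]
    g /= (2.0 * area)[:, None, None]
    return area, g


def stiffness_p1(cells, area, grads, K_cells) -> sp.csr_matrix:
    """Assemble int grad(phi_i) . K grad(phi_j) with per-cell 2x2 K."""
    K = np.asarray(K_cells, dtype=float)
    if K.ndim == 2:
        K = np.broadcast_to(K, (len(cells), 2, 2))
    loc = np.einsum("m,mia,mab,mjb->mij", area, grads, K, grads)
    i = np.repeat(cells, 3, axis=1).ravel()
    j = np.tile(cells, (1, 3)).ravel()
    n = cells.max() + 1
    return sp.coo_matrix((loc.ravel(), (i, j)), shape=(n, n)).tocsr()


def advection_p1(cells, area, grads, v_cells) -> sp.csr_matrix:
    """Non-conservative advection int phi_i (v . grad phi_j), per-cell v."""
    vg = np.einsum("ma,mja->mj", np.asarray(v_cells, dtype=float), grads)
    loc = (area / 3.0)[:, None, None] * vg[:, None, :] * np.ones((1, 3, 1))
    i = np.repeat(cells, 3, axis=1).ravel()
    j = np.tile(cells, (1, 3)).ravel()
    n = cells.max() + 1
    return sp.coo_matrix((loc.ravel(), (i, j)), shape=(n, n)).tocsr()


def lumped_mass_p1(cells, area, coef_cells=None, n_nodes=None) -> np.ndarray:
    """Diagonal (lumped) mass vector; optional per-cell coefficient."""
    w = area / 3.0 if coef_cells is None else area * np.asarray(coef_cells) / 3.0
    n = (cells.max() + 1) if n_nodes is None else n_nodes
    d = np.zeros(n)
    np.add.at(d, cells.ravel(), np.repeat(w, 3))
    return d


def scatter_p1(cells, area, s_cells, n_nodes=None) -> np.ndarray:
    """Load vector int s phi_i for piecewise-constant source s."""
    return lumped_mass_p1(cells, area, s_cells, n_nodes)


def cell_average(cells, nodal: np.ndarray) -> np.ndarray:
    return nodal[cells].mean(axis=1)


def nodal_projection(cells, area, cell_vals: np.ndarray, n_nodes: int) -> np.ndarray:
    """Volume-weighted projection of cellwise values onto vertices."""
    num = scatter_p1(cells, area, cell_vals, n_nodes)
    den = lumped_mass_p1(cells, area, None, n_nodes)
    return num / den


def apply_dirichlet(A: sp.spmatrix, b: np.ndarray, nodes: np.ndarray,
                    values: np.ndarray):
    """Strongly impose A[n,:] = e_n, b[n] = value."""
    A = A.tolil()
    A[nodes, :] = 0.0
    A[nodes, nodes] = 1.0
    b = b.copy()
    b[nodes] = values
    return A.tocsr(), b


# ---------------------------------------------------------------------------
# P2 (Taylor-Hood displacement) kernels
# ---------------------------------------------------------------------------

@dataclass
class P2Space:
    coords: np.ndarray        # (N2, 2) vertices then edge midpoints
    cells6: np.ndarray        # (M, 6): v0 v1 v2, mid01 mid12 mid20
    n_vertices: int
    edge_mid: dict            # (a, b) sorted vertex pair -> midpoint index


def build_p2_space(verts: np.ndarray, cells: np.ndarray) -> P2Space:
    edge_mid: dict = {}
    coords = [verts]
    nxt = len(verts)
    cells6 = np.empty((len(cells), 6), dtype=np.int64)
    cells6[:, :3] = cells
    for ci, tri in enumerate(cells):
        for k, (a, b) in enumerate(((0, 1), (1, 2), (2, 0))):
            key = tuple(sorted((tri[a], tri[b])))
            m = edge_mid.get(key)
            if m is None:
                m = nxt
                edge_mid[key] = m
                coords.append(0.5 * (verts[key[0]] + verts[key[1]])[None, :])
                nxt += 1
            cells6[ci, 3 + k] = m
    return P2Space(np.concatenate(coords, axis=0), cells6, len(verts), edge_mid)


# quadrature: 3 edge-midpoint points, exact for degree 2
_QP_L = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])


def _p2_grads_at(L, gL):
    """P2 shape gradients at barycentric point L; gL is (M, 3, 2)."""
    M = gL.shape[0]
    g = np.zeros((M, 6, 2))
    for i in range(3):
        g[:, i] = (4.0 * L[i] - 1.0) * gL[:, i]
    pairs = ((0, 1), (1, 2), (2, 0))
    for k, (i, j) in enumerate(pairs):
        g[:, 3 + k] = 4.0 * (L[i] * gL[:, j] + L[j] * gL[:, i])
    return g


def elasticity_p2(space: P2Space, area, gL, lam: float, mu: float) -> sp.csr_matrix:
    """Plane-strain linear elasticity stiffness on P2 vector elements."""
    M = len(space.cells6)
    D = np.array([[lam + 2 * mu, lam, 0.0],
                  [lam, lam + 2 * mu, 0.0],
                  [0.0, 0.0, mu]])
    Kloc = np.zeros((M, 12, 12))
    for L in _QP_L:
        g = _p2_grads_at(L, gL)  # (M, 6, 2)
        B = np.zeros((M, 3, 12))
        B[:, 0, 0::2] = g[:, :, 0]
        B[:, 1, 1::2] = g[:, :, 1]
        B[:, 2, 0::2] = g[:, :, 1]
        B[:, 2, 1::2] = g[:, :, 0]
        Kloc += np.einsum("m,mki,kl,mlj->mij", area / 3.0, B, D, B)
    dof = np.empty((M, 12), dtype=np.int64)
    dof[:, 0::2] = 2 * space.cells6
    dof[:, 1::2] = 2 * space.cells6 + 1
    i = np.repeat(dof, 12, axis=1).ravel()
    j = np.tile(dof, (1, 12)).ravel()
    n = 2 * len(space.coords)
    return sp.coo_matrix((Kloc.ravel(), (i, j)), shape=(n, n)).tocsr()


def pressure_load_p2(space: P2Space, cells, area, gL, p_nodal) -> np.ndarray:
    """Load vector int p div(delta u) dv coupling P1 pressure to P2 u."""
    M = len(space.cells6)
    f = np.zeros(2 * len(space.coords))
    dof = np.empty((M, 12), dtype=np.int64)
    dof[:, 0::2] = 2 * space.cells6
    dof[:, 1::2] = 2 * space.cells6 + 1
    for L in _QP_L:
        g = _p2_grads_at(L, gL)
        p_q = p_nodal[cells] @ L  # P1 interpolation at the quadrature point
        loc = np.zeros((M, 12))
        loc[:, 0::2] = g[:, :, 0]
        loc[:, 1::2] = g[:, :, 1]
        loc *= (area / 3.0 * p_q)[:, None]
        np.add.at(f, dof.ravel(), loc.ravel())
    return f


def div_u_cells(space: P2Space, area, gL, u: np.ndarray) -> np.ndarray:
    """Cell-averaged divergence of a P2 vector field (exact cell mean)."""
    ux = u[0::2][space.cells6]
    uy = u[1::2][space.cells6]
    div = np.zeros(len(space.cells6))
    for L in _QP_L:
        g = _p2_grads_at(L, gL)
        div += (np.einsum("mi,mi->m", ux, g[:, :, 0])
                + np.einsum("mi,mi->m", uy, g[:, :, 1])) / 3.0
    return div


def p2_boundary_dofs(space: P2Space, mesh: LobuleMesh, tags) -> np.ndarray:
    """All displacement DOFs (x and y) on boundary edges with given tags."""
    if isinstance(tags, str):
        tags = (tags,)
    mask = np.isin(mesh.boundary_tags, list(tags))
    nodes = set(np.unique(mesh.boundary_edges[mask]).tolist())
    for e in mesh.boundary_edges[mask]:
        nodes.add(space.edge_mid[tuple(sorted(e))])
    nodes = np.array(sorted(nodes), dtype=np.int64)
    return np.concatenate([2 * nodes, 2 * nodes + 1])


# ---------------------------------------------------------------------------
# generic Newton driver
# ---------------------------------------------------------------------------

def newton_solve(residual, jacobian, x0, tol: float = 1e-10, maxit: int = 25,
                 atol: float = 0.0):
    """Monolithic Newton iteration with sparse direct linear solves.

    Converges when ||r|| <= max(tol * ||r0||, atol); returns (x, info) with
    the iteration count and final relative residual.  The blocks of the
    staggered scheme are affine, so they converge in one iteration; the
    generic driver also serves nonlinear sub-problems.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = residual(x)
    norm0 = np.linalg.norm(r)
    if norm0 <= atol:
        return x, {"iterations": 0, "rel_residual": 0.0}
    for it in range(1, maxit + 1):
        J = jacobian(x)
        dx = spla.spsolve(sp.csr_matrix(J), r)
        x = x - dx
        r = residual(x)
        nr = np.linalg.norm(r)
        rel = nr / norm0
        if nr <= max(tol * norm0, atol):
            return x, {"iterations": it, "rel_residual": float(rel)}
    raise SolverError(f"Newton failed: rel_residual={rel:.3e} after {maxit} its")


# ---------------------------------------------------------------------------
# state containers and settings
# ---------------------------------------------------------------------------

@dataclass
class SolverSettings:
    dt: float = 10.0
    t_end: float = 1610.0
    newton_tol: float = 1e-10
    newton_maxit: int = 25
    time_integrator: str = "backward_euler"  # displacement: also "newmark"
    newmark_beta: float = 0.25
    newmark_gamma: float = 0.5
    quadrature_order: int = 2
    n_sub_cell: int = 5
    displacement: bool = True
    output_times: tuple = (0.0, 200.0, 500.0, 1000.0, 1610.0)
    uptake_limiter: float = 0.5  # max fraction of local solute removable per step

    def __post_init__(self):
        if self.dt <= 0 or self.newton_tol <= 0:
            raise SolverError("dt and tolerances must be positive")
        if self.time_integrator not in ("backward_euler", "newmark"):
            raise SolverError("unknown time integrator")


@dataclass
class MacroState:
    """Nodal fields of the macro DOF set at one time level."""

    t: float
    u: np.ndarray                  # (2*N2,) P2 displacement DOFs
    p: np.ndarray                  # (N,) pore pressure
    n_S: np.ndarray                # (N,)
    n_T: np.ndarray                # (N,)
    conc: dict = field(default_factory=dict)   # solute name -> (N,) mol/m^3
    q_cells: np.ndarray | None = None          # (M, 2) filter velocity
    rho_hat_T_cells: np.ndarray | None = None  # (M,) fat production

    @property
    def n_F(self) -> np.ndarray:
        return 1.0 - self.n_S - self.n_T

    def mu(self, name: str, spec, params) -> np.ndarray:
        return con.chemical_potential(self.conc[name], spec, params)

    def copy(self) -> "MacroState":
        return MacroState(
            t=self.t, u=self.u.copy(), p=self.p.copy(), n_S=self.n_S.copy(),
            n_T=self.n_T.copy(), conc={k: v.copy() for k, v in self.conc.items()},
            q_cells=None if self.q_cells is None else self.q_cells.copy(),
            rho_hat_T_cells=(None if self.rho_hat_T_cells is None
                             else self.rho_hat_T_cells.copy()),
        )

    def check_finite(self):
        for name, arr in (("u", self.u), ("p", self.p), ("n_S", self.n_S),
                          ("n_T", self.n_T)):
            if not np.all(np.isfinite(arr)):
                raise SolverError(f"non-finite values in field {name}")
        nf = self.n_F
        if np.any(nf <= 0.0) or np.any(nf >= 1.0):
            raise SolverError("fluid fraction left (0, 1); step aborted")


@dataclass
class BoundaryConditions:
    """Strong (Dirichlet) data assembled by the scenario layer."""

    pressure_nodes: np.ndarray
    pressure_values: np.ndarray
    solute_nodes: dict = field(default_factory=dict)   # name -> node array
    solute_values: dict = field(default_factory=dict)  # name -> value array
    fixed_displacement_tags: tuple = ("inflow_portal", "inflow_venule",
                                      "outflow_central")


# ---------------------------------------------------------------------------
# stationary Darcy
# ---------------------------------------------------------------------------

def darcy_system(mesh: LobuleMesh, params: con.MaterialParams,
                 n_F_cells, source_cells=None):
    area, grads = p1_geometry(mesh.vertices, mesh.cells)
    K_cells = con.permeability_tensor(n_F_cells, mesh.aniso_dir, params)
    A = stiffness_p1(mesh.cells, area, grads, K_cells)
    b = np.zeros(len(mesh.vertices))
    if source_cells is not None:
        b += scatter_p1(mesh.cells, area, source_cells, len(mesh.vertices))
    return A, b, K_cells, area, grads


def solve_stationary_darcy(mesh: LobuleMesh, params: con.MaterialParams,
                           bc_nodes, bc_values, n_F=None, source_cells=None,
                           settings: SolverSettings | None = None):
    """Rigid-skeleton stationary Darcy limit.

    Returns (p, q_cells, info): pore pressure, per-cell filter velocity
    n_F w_FS = -K grad p, and the Newton report (one iteration: the problem
    is linear).
    """
    bc_nodes = np.asarray(bc_nodes, dtype=np.int64)
    if bc_nodes.size == 0:
        raise SolverError("all-Neumann Darcy problem is singular: "
                          "at least one Dirichlet pressure node is required")
    settings = settings or SolverSettings()
    if n_F is None:
        n_F_cells = np.full(len(mesh.cells), params.n0_F)
    else:
        n_F = np.asarray(n_F, dtype=float)
        n_F_cells = cell_average(mesh.cells, n_F) if n_F.ndim and len(n_F) == len(
            mesh.vertices) else np.broadcast_to(n_F, (len(mesh.cells),)).copy()
    A, b, K_cells, area, grads = darcy_system(mesh, params, n_F_cells, source_cells)
    A, b = apply_dirichlet(A, b, bc_nodes, np.asarray(bc_values, dtype=float))
    p, info = newton_solve(lambda x: A @ x - b, lambda x: A,
                           np.zeros(len(b)), tol=settings.newton_tol,
                           maxit=settings.newton_maxit,
                           atol=1e-12 * (1.0 + np.linalg.norm(b)))
    gp = np.einsum("mia,mi->ma", grads, p[mesh.cells])
    q_cells = -np.einsum("mab,mb->ma", K_cells, gp)
    diss = con.darcy_dissipation(K_cells, gp)
    if np.any(diss < -1e-25):
        raise SolverError("negative Darcy dissipation (non-SPD permeability?)")
    info = dict(info, dissipation_min=float(diss.min()))
    return p, q_cells, info


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------

def streamlines(mesh: LobuleMesh, q_cells: np.ndarray, seeds: np.ndarray,
                step_frac: float = 0.25, max_steps: int = 4000,
                terminal_lobules=None):
    """Trace the filter-velocity field from seed points.

    Velocity lookup is nearest-cell (the field is piecewise constant);
    integration is RK2.  A line terminates when it enters an open
    central-vein disc (reported as that lobule's id), leaves the domain, or
    stagnates.  By default only lobules whose vein rim carries an outflow
    tag are terminals (an obstructed, sealed vein does not swallow lines).
    Returns a list of (polyline, terminal_lobule_or_None).
    """
    if terminal_lobules is None:
        from .mesh import TAG_OUTFLOW_CENTRAL, _owning_lobule_of_edges
        owners = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id,
                                         mesh.boundary_edges)
        terminal_lobules = set(
            owners[mesh.boundary_tags == TAG_OUTFLOW_CENTRAL].tolist())
    terminal_lobules = set(int(t) for t in terminal_lobules)
    cen = mesh.cell_centroids()
    tree = cKDTree(cen)
    h = float(np.sqrt(np.median(mesh.cell_areas())))
    ds = step_frac * h
    speed = np.linalg.norm(q_cells, axis=1)
    v_stop = 1e-6 * max(speed.max(), 1e-300)
    r_cv = mesh.meta.get("r_central_vein", 0.1 * mesh.circumradius)
    out = []
    for seed in np.atleast_2d(seeds):
        x = np.asarray(seed, dtype=float).copy()
        line = [x.copy()]
        terminal = None
        for _ in range(max_steps):
            d_cv = np.linalg.norm(mesh.lobule_centers - x[None, :], axis=1)
            li = int(np.argmin(d_cv))
            if d_cv[li] < 1.25 * r_cv and li in terminal_lobules:
                terminal = li
                break
            d, ci = tree.query(x)
            if d > 2.5 * h:
                break  # left the domain
            v = q_cells[ci]
            sp_ = np.linalg.norm(v)
            if sp_ < v_stop:
                break
            xm = x + 0.5 * ds * v / sp_
            _, cm = tree.query(xm)
            vm = q_cells[cm]
            spm = np.linalg.norm(vm)
            if spm < v_stop:
                break
            x = x + ds * vm / spm
            line.append(x.copy())
        out.append((np.asarray(line), terminal))
    return out


# ---------------------------------------------------------------------------
# residual assembly (diagnostics / verification)
# ---------------------------------------------------------------------------

def assemble_residual(state: MacroState, prev: MacroState, mesh: LobuleMesh,
                      params: con.MaterialParams, solutes: dict,
                      settings: SolverSettings,
                      rho_hat_T_cells=None, uptake_cells=None,
                      p2: P2Space | None = None):
    """Discrete residual blocks of the coupled weak forms.

    Blocks: 'momentum' (mixture momentum with pressure coupling),
    'mixture_mass' (Darcy + volumetric rate + growth sink), 'n_S', 'n_T'
    (tissue/fat fraction transport), and 'solute_<name>' for each fluid
    solute (storage + advection-diffusion + uptake sink).  Exchange sources
    are supplied per cell.  Raises on NaNs, naming the offending block.
    """
    state.check_finite()
    dt = settings.dt
    N = len(mesh.vertices)
    M = len(mesh.cells)
    area, grads = p1_geometry(mesh.vertices, mesh.cells)
    rho_hat = np.zeros(M) if rho_hat_T_cells is None else np.asarray(rho_hat_T_cells)
    n_F_cells = cell_average(mesh.cells, state.n_F)
    K_cells = con.permeability_tensor(n_F_cells, mesh.aniso_dir, params)

    blocks: dict[str, np.ndarray] = {}

    p2 = p2 or build_p2_space(mesh.vertices, mesh.cells)
    lam_eff = params.lam_S + params.lam_T
    mu_eff = params.mu_S + params.mu_T
    Ku = elasticity_p2(p2, area, grads, lam_eff, mu_eff)
    f_p = pressure_load_p2(p2, mesh.cells, area, grads, state.p)
    blocks["momentum"] = Ku @ state.u - f_p

    divu = div_u_cells(p2, area, grads, state.u)
    divu_prev = div_u_cells(p2, area, grads, prev.u)
    trD = (divu - divu_prev) / dt
    A = stiffness_p1(mesh.cells, area, grads, K_cells)
    src = rho_hat / params.rho_TR - trD
    blocks["mixture_mass"] = A @ state.p - scatter_p1(mesh.cells, area, src, N)

    mL = lumped_mass_p1(mesh.cells, area, None, N)
    trD_nodal = nodal_projection(mesh.cells, area, trD, N)
    blocks["n_S"] = mL * ((state.n_S - prev.n_S) / dt + state.n_S * trD_nodal)
    rhoT_nodal = nodal_projection(mesh.cells, area, rho_hat, N)
    blocks["n_T"] = mL * ((state.n_T - prev.n_T) / dt + state.n_T * trD_nodal
                          - rhoT_nodal / params.rho_TR)

    gp = np.einsum("mia,mi->ma", grads, state.p[mesh.cells])
    q_cells = -np.einsum("mab,mb->ma", K_cells, gp)
    for name, spec_ in solutes.items():
        if spec_.carrier != "F":
            c = state.conc.get(name)
            if c is None:
                continue
            blocks[f"solute_{name}"] = mL * state.n_S * (c - prev.conc[name]) / dt
            continue
        c = state.conc.get(name)
        if c is None:
            continue
        D_cells = (n_F_cells * spec_.diffusivity)[:, None, None] * np.eye(2)
        Ad = stiffness_p1(mesh.cells, area, grads, D_cells)
        Cv = advection_p1(mesh.cells, area, grads, spec_.advect_factor * q_cells)
        sink = np.zeros(N)
        if uptake_cells and name in uptake_cells:
            sink = scatter_p1(mesh.cells, area, uptake_cells[name], N)
        nF_nodal = state.n_F
        nF_prev = prev.n_F
        r = mL * (nF_nodal * c - nF_prev * prev.conc[name]) / dt
        r += (Ad + Cv) @ c + sink
        blocks[f"solute_{name}"] = r
    for name, r in blocks.items():
        if not np.all(np.isfinite(r)):
            raise SolverError(f"NaN in residual block {name}")
    return blocks


# ---------------------------------------------------------------------------
# transient driver
# ---------------------------------------------------------------------------

@dataclass
class RunHistory:
    """Raw output of :func:`advance`."""

    snapshots: list            # list[MacroState]
    cell_f: np.ndarray         # final intracellular FFA per cell
    cell_o: np.ndarray
    cell_tg: np.ndarray
    audit: "coupling.MassAudit"
    newton_reports: list
    floor_activations: int = 0
    closure_max: float = 0.0     # max |sum of mass-exchange terms| over run
    saturation_max: float = 0.0  # max |n_S + n_T + n_F - 1| over run


def initial_state(mesh: LobuleMesh, params: con.MaterialParams,
                  initial_conc: dict, p2: P2Space) -> MacroState:
    N = len(mesh.vertices)
    return MacroState(
        t=0.0,
        u=np.zeros(2 * len(p2.coords)),
        p=np.zeros(N),
        n_S=np.full(N, params.n0_S),
        n_T=np.full(N, params.n0_T),
        conc={k: np.asarray(v, dtype=float) * np.ones(N)
              for k, v in initial_conc.items()},
    )


def advance(mesh: LobuleMesh, params: con.MaterialParams,
            kinetics: KineticParams, solutes: dict,
            bcs: BoundaryConditions, settings: SolverSettings,
            initial_conc: dict, transported=("FFA", "Ox"),
            kinetics_on: bool = True, log=None) -> RunHistory:
    """Staggered time integration of the coupled lobule problem.

    Per step: (1) freeze macro plasma concentrations at the quadrature
    points and integrate the cell ODEs over dt, (2) form the mass-exchange
    terms, (3) update the fat fraction, (4) solve the Darcy pressure with
    the growth sink, (5) solve advection-diffusion for each transported
    solute with the uptake sinks, (6) solve the quasi-static displacement.
    """
    area, grads = p1_geometry(mesh.vertices, mesh.cells)
    N = len(mesh.vertices)
    Mc = len(mesh.cells)
    p2 = build_p2_space(mesh.vertices, mesh.cells)
    state = initial_state(mesh, params, initial_conc, p2)
    dt = settings.dt
    n_steps = int(round(settings.t_end / dt))
    out_steps = {int(round(t / dt)) for t in settings.output_times
                 if 0.0 <= t <= settings.t_end + 1e-9}

    # cell states per cell (one quadrature point per triangle)
    f = np.zeros(Mc)
    o = np.zeros(Mc)
    tg = np.full(Mc, params.n0_T * params.rho_TR / params.n0_S)
    tg0 = tg.copy()

    lam_eff = params.lam_S + params.lam_T
    mu_eff = params.mu_S + params.mu_T
    Ku = None
    fixed_dofs = None
    if settings.displacement:
        Ku = elasticity_p2(p2, area, grads, lam_eff, mu_eff)
        fixed_dofs = p2_boundary_dofs(p2, mesh, bcs.fixed_displacement_tags)
        Ku_bc, _ = apply_dirichlet(Ku, np.zeros(2 * len(p2.coords)), fixed_dofs,
                                   np.zeros(len(fixed_dofs)))
        Ku_lu = spla.splu(Ku_bc.tocsc())
    J_nodal = np.ones(N)
    trD_cells = np.zeros(Mc)
    divu_prev = np.zeros(Mc)

    audit = coupling.MassAudit()
    reports = []
    snapshots = []
    closure_max = 0.0
    saturation_max = 0.0
    floor_before = con.chemical_potential_floor_count()

    def solve_pressure(rho_hat_cells):
        n_F_cells = np.clip(cell_average(mesh.cells, state.n_F), 1e-6, 1 - 1e-6)
        src = rho_hat_cells / params.rho_TR - trD_cells
        A, b, K_cells, _, _ = darcy_system(mesh, params, n_F_cells, src)
        A, b = apply_dirichlet(A, b, bcs.pressure_nodes, bcs.pressure_values)
        p, info = newton_solve(lambda x: A @ x - b, lambda x: A, state.p,
                               tol=settings.newton_tol,
                               maxit=settings.newton_maxit,
                               atol=1e-12 * (1.0 + np.linalg.norm(b)))
        gp = np.einsum("mia,mi->ma", grads, p[mesh.cells])
        q = -np.einsum("mab,mb->ma", K_cells, gp)
        return p, q, n_F_cells, info

    # t = 0: hydrostatic pressure from the boundary data, no sources
    state.p, q_cells, n_F_cells, info0 = solve_pressure(np.zeros(Mc))
    reports.append(info0)
    state.q_cells = q_cells
    state.rho_hat_T_cells = np.zeros(Mc)
    if 0 in out_steps:
        snapshots.append(state.copy())

    for step in range(1, n_steps + 1):
        t_new = step * dt
        prev_nF_cells = np.clip(cell_average(mesh.cells, state.n_F), 1e-6, 1)
        n_S_cells = cell_average(mesh.cells, state.n_S)

        # (1) cell-scale solve at frozen plasma values
        if kinetics_on:
            uptake = {}
            for name in transported:
                c_cells = np.maximum(cell_average(mesh.cells, state.conc[name]), 0.0)
                if name == "FFA":
                    raw = kinetics.vmax_FFA * c_cells / (kinetics.KM_FFA + c_cells)
                elif name == "Ox":
                    raw = kinetics.vmax_Ox * c_cells / (kinetics.KM_Ox + c_cells)
                else:
                    raw = np.zeros(Mc)
                # availability limiter: never remove more than a fraction of
                # the locally stored solute in one step
                avail = settings.uptake_limiter * prev_nF_cells * c_cells / (
                    np.maximum(n_S_cells, 1e-12) * dt)
                uptake[name] = np.minimum(raw, avail)
            tg_old = tg.copy()
            f_old = f.copy()
            f, o, tg, integrals = integrate_cells(
                f, o, tg, uptake["FFA"], uptake["Ox"], kinetics, dt,
                n_sub=settings.n_sub_cell)
            cellst, exch = coupling.gauss_point_exchange_arrays(
                f, o, tg, tg_old, uptake, n_S_cells, solutes, kinetics, dt)
            rho_hat_cells = exch.rho_hat_T
            closure_max = max(closure_max, exch.closure_error())
            audit.accumulate(area, n_S_cells, uptake, integrals,
                             tg, tg_old, f, dt, kinetics, f_old=f_old)
        else:
            uptake = {name: np.zeros(Mc) for name in transported}
            rho_hat_cells = np.zeros(Mc)

        # (2-3) fat-fraction update (pointwise backward-Euler source)
        rhoT_nodal = nodal_projection(mesh.cells, area, rho_hat_cells, N)
        trD_nodal = nodal_projection(mesh.cells, area, trD_cells, N)
        state.n_S = params.n0_S / J_nodal
        try:
            state.n_T = coupling.update_fat_fraction(
                state.n_T, rhoT_nodal, params, dt, div_rate=trD_nodal,
                n_S=state.n_S)
        except coupling.CouplingError as exc:
            raise SolverError(f"{exc} at t={t_new:.1f} s") from exc
        saturation_max = max(saturation_max, float(np.max(np.abs(
            state.n_S + state.n_T + state.n_F - 1.0))))
        state.check_finite()

        # (4) Darcy with the growth sink
        state.p, q_cells, n_F_cells, info = solve_pressure(rho_hat_cells)
        reports.append(info)

        # (5) solute transport, backward Euler, implicit in c
        nF_new_nodal = state.n_F
        for name in transported:
            spec_ = solutes[name]
            D_cells = (n_F_cells * spec_.diffusivity)[:, None, None] * np.eye(2)
            Ad = stiffness_p1(mesh.cells, area, grads, D_cells)
            Cv = advection_p1(mesh.cells, area, grads,
                              spec_.advect_factor * q_cells)
            mL_new = lumped_mass_p1(mesh.cells, area,
                                    cell_average(mesh.cells, nF_new_nodal), N)
            mL_old = lumped_mass_p1(mesh.cells, area, prev_nF_cells, N)
            sink = scatter_p1(mesh.cells, area, n_S_cells * uptake[name], N)
            A_sys = sp.diags(mL_new / dt) + Ad + Cv
            b_sys = mL_old * state.conc[name] / dt - sink
            nodes = bcs.solute_nodes.get(name, np.empty(0, dtype=np.int64))
            vals = bcs.solute_values.get(name, np.empty(0))
            A_sys, b_sys = apply_dirichlet(A_sys, b_sys, nodes, vals)
            c_new = spla.spsolve(A_sys.tocsr(), b_sys)
            state.conc[name] = np.maximum(c_new, 0.0)

        # (6) quasi-static displacement (Taylor-Hood pairing)
        if settings.displacement:
            f_p = pressure_load_p2(p2, mesh.cells, area, grads, state.p)
            f_p[fixed_dofs] = 0.0
            u_new = Ku_lu.solve(f_p)
            divu = div_u_cells(p2, area, grads, u_new)
            trD_cells = (divu - divu_prev) / dt
            divu_prev = divu
            state.u = u_new
            J_cells = 1.0 + divu
            J_nodal = np.clip(nodal_projection(mesh.cells, area, J_cells, N),
                              0.5, 2.0)

        state.t = t_new
        state.q_cells = q_cells
        state.rho_hat_T_cells = rho_hat_cells
        if log is not None:
            log(step, t_new, info)
        if step in out_steps:
            snapshots.append(state.copy())

    return RunHistory(
        snapshots=snapshots, cell_f=f, cell_o=o, cell_tg=tg, audit=audit,
        newton_reports=reports,
        floor_activations=con.chemical_potential_floor_count() - floor_before,
        closure_max=closure_max, saturation_max=saturation_max,
    )
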