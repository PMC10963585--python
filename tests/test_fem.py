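"""Finite-element machinery: Darcy oracles, convergence, conservation."""

import numpy as np
import pytest

import lobulefem as lf
from lobulefem import fem
from lobulefem.cell import KineticParams
from lobulefem.mesh import annulus_mesh, rectangle_mesh

from conftest import R, darcy_bc

P = lf.MaterialParams()
P_ISO = P.replace(aniso_weight=0.0)


# ---------------------------------------------------------------------------
# stationary Darcy oracles
# ---------------------------------------------------------------------------

class TestStationaryDarcy:
    def test_linear_problem_converges_in_one_newton_iteration(self):
        mesh = rectangle_mesh(1e-3, 2e-4, 20, 4)
        nodes, vals = darcy_bc(mesh)
        _, _, info = lf.solve_stationary_darcy(mesh, P_ISO, nodes, vals)
        assert info["iterations"] == 1

    def test_equal_pressures_give_zero_velocity(self):
        mesh = rectangle_mesh(1e-3, 2e-4, 20, 4)
        nodes, _ = darcy_bc(mesh)
        p, q, _ = lf.solve_stationary_darcy(mesh, P_ISO, nodes,
                                            np.full(len(nodes), 50.0))
        assert np.allclose(p, 50.0)
        assert np.max(np.abs(q)) < 1e-20

    def test_strip_matches_analytic_darcy(self):
        # uniform velocity K dp/L for a pressure drop over a strip
        L = 1e-3
        mesh = rectangle_mesh(L, 2e-4, 40, 8)
        nodes, vals = darcy_bc(mesh, p_in=133.0, p_out=0.0)
        p, q, _ = lf.solve_stationary_darcy(mesh, P_ISO, nodes, vals)
        v_exact = P_ISO.darcy_mobility * 133.0 / L
        assert np.max(np.abs(q[:, 0] - v_exact)) / v_exact < 1e-3
        assert np.max(np.abs(q[:, 1])) / v_exact < 1e-10

    def test_annulus_matches_log_solution(self):
        r0, r1 = 1e-4, 5e-4
        mesh = annulus_mesh(r0, r1, 24, 96)
        nodes, vals = darcy_bc(mesh, p_in=133.0, p_out=0.0)
        p, _, _ = lf.solve_stationary_darcy(mesh, P_ISO, nodes, vals)
        r = np.linalg.norm(mesh.vertices, axis=1)
        p_exact = 133.0 * np.log(r / r0) / np.log(r1 / r0)
        err = np.linalg.norm(p - p_exact) / np.linalg.norm(p_exact)
        assert err < 0.01

    def test_all_neumann_is_rejected(self):
        mesh = rectangle_mesh(1e-3, 2e-4, 10, 2)
        with pytest.raises(fem.SolverError):
            lf.solve_stationary_darcy(mesh, P_ISO, np.empty(0, dtype=np.int64),
                                      np.empty(0))

    def test_maximum_principle_on_lobule(self, single_mesh):
        nodes, vals = darcy_bc(single_mesh)
        p, _, _ = lf.solve_stationary_darcy(single_mesh, P, nodes, vals)
        assert p.max() == pytest.approx(133.0, rel=5e-3)
        assert p.min() == pytest.approx(0.0, abs=5e-3 * 133.0)
        assert np.all(p <= 133.0 + 1e-9) and np.all(p >= -1e-9)


class TestManufacturedSolutionConvergence:
    def solve_mms(self, n):
        L = 1e-3
        mesh = rectangle_mesh(L, L, n, n)
        area, grads = fem.p1_geometry(mesh.vertices, mesh.cells)
        k = P_ISO.darcy_mobility
        A = fem.stiffness_p1(mesh.cells, area, grads, k * np.eye(2))
        x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
        p_exact = np.sin(np.pi * x / L) * np.sin(np.pi * y / L)
        cen = mesh.cell_centroids()
        f = 2 * (np.pi / L) ** 2 * k * np.sin(np.pi * cen[:, 0] / L) \
            * np.sin(np.pi * cen[:, 1] / L)
        b = fem.scatter_p1(mesh.cells, area, f, len(mesh.vertices))
        bnodes = np.unique(mesh.boundary_edges)
        A, b = fem.apply_dirichlet(A, b, bnodes, p_exact[bnodes])
        import scipy.sparse.linalg as spla
        p = spla.spsolve(A, b)
        mL = fem.lumped_mass_p1(mesh.cells, area, None, len(mesh.vertices))
        return float(np.sqrt(np.sum(mL * (p - p_exact) ** 2)))

    def test_second_order_l2_convergence(self):
        errs = [self.solve_mms(n) for n in (8, 16, 32)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 1.9)


# ---------------------------------------------------------------------------
# residual assembly
# ---------------------------------------------------------------------------

class TestAssembleResidual:
    def make_state(self, mesh, solutes, conc=None):
        p2 = fem.build_p2_space(mesh.vertices, mesh.cells)
        st = fem.initial_state(mesh, P, conc or {"FFA": 1.0, "Ox": 0.05}, p2)
        return st, p2

    def test_reference_state_is_in_equilibrium(self, coarse_mesh, solutes):
        st, p2 = self.make_state(coarse_mesh, solutes)
        blocks = fem.assemble_residual(st, st.copy(), coarse_mesh, P, solutes,
                                       fem.SolverSettings(), p2=p2)
        for name, r in blocks.items():
            assert np.linalg.norm(r) < 1e-12, name

    def test_growth_source_single_term_oracle(self, coarse_mesh, solutes):
        # uniform fat production, all else frozen: the fat-fraction block
        # must equal -(rho_hat_T / rho_TR) times the test-function integrals
        st, p2 = self.make_state(coarse_mesh, solutes)
        rho_hat = np.full(len(coarse_mesh.cells), 0.03)
        blocks = fem.assemble_residual(st, st.copy(), coarse_mesh, P, solutes,
                                       fem.SolverSettings(),
                                       rho_hat_T_cells=rho_hat, p2=p2)
        area, _ = fem.p1_geometry(coarse_mesh.vertices, coarse_mesh.cells)
        expect = -fem.scatter_p1(coarse_mesh.cells, area,
                                 rho_hat / P.rho_TR,
                                 len(coarse_mesh.vertices))
        assert np.allclose(blocks["n_T"], expect, rtol=1e-12)

    def test_nan_state_is_identified(self, coarse_mesh, solutes):
        st, p2 = self.make_state(coarse_mesh, solutes)
        st.p[0] = np.nan
        with pytest.raises(fem.SolverError):
            fem.assemble_residual(st, st.copy(), coarse_mesh, P, solutes,
                                  fem.SolverSettings(), p2=p2)


class TestPatchTest:
    def test_constant_pressure_balances_boundary_traction(self, coarse_mesh):
        """Total stress -p I with constant p is an exact discrete
        equilibrium once the consistent boundary traction t = -p n is
        applied (Taylor-Hood displacement space)."""
        mesh = coarse_mesh
        p0 = 133.0
        area, grads = fem.p1_geometry(mesh.vertices, mesh.cells)
        p2 = fem.build_p2_space(mesh.vertices, mesh.cells)
        f_int = fem.pressure_load_p2(p2, mesh.cells, area, grads,
                                     np.full(len(mesh.vertices), p0))
        # consistent traction load on P2 edges: int N_i ds weights (1/6,1/6,2/3)
        f_trac = np.zeros_like(f_int)
        cen_map = {}
        for ci, tri in enumerate(mesh.cells):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                cen_map[tuple(sorted((tri[a], tri[b])))] = ci
        centroids = mesh.cell_centroids()
        for e in mesh.boundary_edges:
            a, b = e
            m = p2.edge_mid[tuple(sorted(e))]
            t_vec = mesh.vertices[b] - mesh.vertices[a]
            ell = np.linalg.norm(t_vec)
            n_vec = np.array([t_vec[1], -t_vec[0]]) / ell
            c = centroids[cen_map[tuple(sorted(e))]]
            mid = 0.5 * (mesh.vertices[a] + mesh.vertices[b])
            if n_vec @ (mid - c) < 0:
                n_vec = -n_vec
            trac = -p0 * n_vec
            for node, w in ((a, ell / 6), (b, ell / 6), (m, 2 * ell / 3)):
                f_trac[2 * node:2 * node + 2] += w * trac
        # momentum residual of u = 0: K u - f_int - f_trac = 0
        resid = -f_int - f_trac
        scale = np.linalg.norm(f_trac)
        assert np.linalg.norm(resid) < 1e-10 * scale

    def test_no_pressure_checkerboard(self, coarse_mesh):
        """No spurious interior extrema: every interior pressure value lies
        within the range of its neighbours (checkerboard modes would
        violate this everywhere)."""
        nodes, vals = darcy_bc(coarse_mesh)
        p, _, _ = lf.solve_stationary_darcy(coarse_mesh, P, nodes, vals)
        cells = coarse_mesh.cells
        n = len(p)
        neighbors = [set() for _ in range(n)]
        for tri in cells:
            for a in tri:
                neighbors[a].update(int(v) for v in tri if v != a)
        interior = np.setdiff1d(np.arange(n),
                                np.unique(coarse_mesh.boundary_edges))
        eps = 1e-9 * 133.0
        for i in interior:
            vals_nb = p[list(neighbors[i])]
            assert p[i] <= vals_nb.max() + eps
            assert p[i] >= vals_nb.min() - eps


# ---------------------------------------------------------------------------
# transient driver
# ---------------------------------------------------------------------------

def tiny_run(dt, t_end=200.0, kinetics=None, kinetics_on=True,
             inflow=None, edge=R / 8, displacement=True):
    mesh = lf.build_single_lobule(target_edge_length=edge)
    inflow = inflow or {"FFA": 3.0, "Ox": 0.091}
    nodes_in = mesh.boundary_nodes(("inflow_portal", "inflow_venule"))
    nodes_out = mesh.boundary_nodes("outflow_central")
    bcs = fem.BoundaryConditions(
        pressure_nodes=np.concatenate([nodes_in, nodes_out]),
        pressure_values=np.concatenate([np.full(len(nodes_in), 133.0),
                                        np.zeros(len(nodes_out))]),
        solute_nodes={k: nodes_in for k in inflow},
        solute_values={k: np.full(len(nodes_in), v) for k, v in inflow.items()},
    )
    settings = fem.SolverSettings(dt=dt, t_end=t_end, output_times=(0.0, t_end),
                                  displacement=displacement)
    init = {k: 0.03 * v for k, v in inflow.items()}
    return mesh, fem.advance(mesh, P, kinetics or KineticParams(),
                             lf.default_solutes(), bcs, settings, init,
                             kinetics_on=kinetics_on)


class TestAdvance:
    def test_zero_kinetics_is_a_fixed_point(self):
        # rigid-skeleton limit: with all rates off nothing may evolve
        mesh, hist = tiny_run(dt=20.0, kinetics_on=False, displacement=False)
        first, last = hist.snapshots[0], hist.snapshots[-1]
        assert np.max(np.abs(last.n_T - P.n0_T)) < 1e-10
        assert np.max(np.abs(last.p - first.p)) < 1e-8 * 133.0

    def test_pressure_extremes_attained_on_boundary(self):
        mesh, hist = tiny_run(dt=20.0, kinetics_on=False)
        p = hist.snapshots[-1].p
        assert (p.max() - p.min()) == pytest.approx(133.0, rel=5e-3)

    def test_saturation_preserved(self):
        mesh, hist = tiny_run(dt=20.0)
        last = hist.snapshots[-1]
        total = last.n_S + last.n_T + last.n_F
        assert np.max(np.abs(total - 1.0)) < 1e-12
        assert np.all(last.n_F > 0) and np.all(last.n_F < 1)

    def test_first_order_time_convergence(self):
        # Richardson check against a fine-step reference
        _, ref = tiny_run(dt=2.5)
        nT_ref = ref.snapshots[-1].n_T
        errs = []
        for dt in (20.0, 10.0, 5.0):
            _, hist = tiny_run(dt=dt)
            errs.append(np.max(np.abs(hist.snapshots[-1].n_T - nT_ref)))
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all(ratios > 1.5), ratios  # ~2 for a first-order scheme

    def test_fat_mass_conservation_audit(self):
        # total TG mass gain equals the integrated production source
        mesh, hist = tiny_run(dt=10.0, t_end=400.0)
        area, _ = fem.p1_geometry(mesh.vertices, mesh.cells)
        nT0, nT1 = hist.snapshots[0].n_T, hist.snapshots[-1].n_T
        nT_cells = lambda v: v[mesh.cells].mean(axis=1)
        gain = float(np.sum(area * (nT_cells(nT1) - nT_cells(nT0))) * P.rho_TR)
        assert gain == pytest.approx(hist.audit.tg_gain_kg, rel=0.01)

    def test_uniform_dirichlet_keeps_concentration_uniform(self):
        # sources off and equal boundary/initial data: no spurious transport
        mesh = lf.build_single_lobule(target_edge_length=R / 8)
        nodes_in = mesh.boundary_nodes(("inflow_portal", "inflow_venule"))
        nodes_out = mesh.boundary_nodes("outflow_central")
        bcs = fem.BoundaryConditions(
            pressure_nodes=np.concatenate([nodes_in, nodes_out]),
            pressure_values=np.concatenate([np.full(len(nodes_in), 133.0),
                                            np.zeros(len(nodes_out))]),
            solute_nodes={"FFA": nodes_in, "Ox": nodes_in},
            solute_values={"FFA": np.full(len(nodes_in), 2.0),
                           "Ox": np.full(len(nodes_in), 0.05)},
        )
        settings = fem.SolverSettings(dt=20.0, t_end=200.0,
                                      output_times=(200.0,),
                                      displacement=False)
        hist = fem.advance(mesh, P, KineticParams(), lf.default_solutes(),
                           bcs, settings, {"FFA": 2.0, "Ox": 0.05},
                           kinetics_on=False)
        last = hist.snapshots[-1]
        assert np.max(np.abs(last.conc["FFA"] - 2.0)) < 1e-9
        assert np.max(np.abs(last.conc["Ox"] - 0.05)) < 1e-10


class TestTransportOracle:
    def test_strip_matches_1d_finite_difference(self):
        """Advection-diffusion down a strip against an independent 1D
        finite-difference reference (same PDE, 401 nodes)."""
        L, W = 1e-3, 1e-4
        nx = 50
        mesh = rectangle_mesh(L, W, nx, 3)
        nodes_in = mesh.boundary_nodes("inflow_portal")
        nodes_out = mesh.boundary_nodes("outflow_central")
        bcs = fem.BoundaryConditions(
            pressure_nodes=np.concatenate([nodes_in, nodes_out]),
            pressure_values=np.concatenate([np.full(len(nodes_in), 133.0),
                                            np.zeros(len(nodes_out))]),
            solute_nodes={"FFA": nodes_in},
            solute_values={"FFA": np.ones(len(nodes_in))},
        )
        dt, t_end = 10.0, 2000.0
        settings = fem.SolverSettings(dt=dt, t_end=t_end, displacement=False,
                                      output_times=(t_end,))
        hist = fem.advance(mesh, P_ISO, KineticParams(), lf.default_solutes(),
                           bcs, settings, {"FFA": 0.0},
                           transported=("FFA",), kinetics_on=False)
        c_fem = hist.snapshots[-1].conc["FFA"]

        # 1D reference: n_F c_t + q c_x = n_F D c_xx, c(0)=1, c_x(L)=0
        D = lf.default_solutes()["FFA"].diffusivity
        q = P_ISO.darcy_mobility * 133.0 / L
        n_F = P_ISO.n0_F
        n1d = 401
        x = np.linspace(0, L, n1d)
        dx = x[1] - x[0]
        main = np.zeros((n1d, n1d))
        for i in range(1, n1d - 1):
            main[i, i - 1] = -q / (2 * dx) - n_F * D / dx ** 2
            main[i, i] = 2 * n_F * D / dx ** 2
            main[i, i + 1] = q / (2 * dx) - n_F * D / dx ** 2
        c = np.zeros(n1d)
        I_nf = n_F * np.eye(n1d)
        A = I_nf + dt * main
        A[0] = 0.0
        A[0, 0] = 1.0
        A[-1] = 0.0
        # outflow: one-sided advection, zero diffusive flux
        A[-1, -1] = n_F + dt * q / dx
        A[-1, -2] = -dt * q / dx
        for _ in range(int(t_end / dt)):
            rhs = n_F * c
            rhs[0] = 1.0
            rhs[-1] = n_F * c[-1]
            c = np.linalg.solve(A, rhs)
        c_ref = np.interp(mesh.vertices[:, 0], x, c)
        err = np.linalg.norm(c_fem - c_ref) / np.linalg.norm(c_ref)
        assert err < 0.01
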