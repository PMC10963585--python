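"""Material laws of the tri-phasic mixture."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lobulefem.constitutive as con

P = con.MaterialParams()


class TestMaterialParams:
    def test_table_defaults(self):
        assert P.n0_S + P.n0_T + P.n0_F == pytest.approx(1.0, abs=1e-15)
        assert P.n0_F == pytest.approx(0.18)
        assert P.k_D == pytest.approx(4.5e-10)

    def test_saturation_violation_rejected(self):
        with pytest.raises(con.ParameterError):
            con.MaterialParams(n0_S=0.8, n0_T=0.1, n0_F=0.18)

    @pytest.mark.parametrize("field", ["lam_S", "mu_T", "theta", "k_D", "rho_FR"])
    def test_nonpositive_constants_rejected(self, field):
        with pytest.raises(con.ParameterError):
            con.MaterialParams(**{field: 0.0})


class TestSolidFatStress:
    def test_reference_state_is_stress_free(self):
        kin = con.LocalKinematics()
        assert np.allclose(con.solid_fat_stress(kin, P), 0.0, atol=1e-12)

    def test_pure_pressure(self):
        kin = con.LocalKinematics(lam=133.0)
        expect = -133.0 * (kin.n_S + kin.n_T) * np.eye(2)
        assert np.allclose(con.solid_fat_stress(kin, P), expect, atol=1e-10)

    def test_small_strain_matches_linear_elasticity(self):
        # series-expansion oracle: sigma = lam_eff tr(eps) I + 2 mu_eff eps
        eps = 1e-4
        kin = con.LocalKinematics(F_S=np.diag([1.0 + eps, 1.0]))
        sig = con.solid_fat_stress(kin, P)
        lam_eff = P.lam_S + P.lam_T
        mu_eff = P.mu_S + P.mu_T
        sig_lin = lam_eff * eps * np.eye(2) + 2 * mu_eff * np.diag([eps, 0.0])
        assert np.max(np.abs(sig - sig_lin)) < 10 * (lam_eff + 2 * mu_eff) * eps ** 2

    def test_symmetry(self):
        F = np.array([[1.01, 0.003], [0.001, 0.995]])
        kin = con.LocalKinematics(F_S=F, lam=50.0)
        sig = con.solid_fat_stress(kin, P)
        assert np.max(np.abs(sig - sig.T)) < 1e-12 * np.max(np.abs(sig))

    def test_inverted_kinematics_rejected(self):
        kin = con.LocalKinematics(F_S=np.diag([-1.0, 1.0]))
        with pytest.raises(con.KinematicsError):
            con.solid_fat_stress(kin, P)


class TestFluidStress:
    def test_zero_pressure_zero_stress(self):
        assert np.allclose(con.fluid_stress(0.18, 0.0, 0.0), 0.0)

    def test_table_value(self):
        # n_F = 0.18 at the 1 mmHg pressure difference
        sig = con.fluid_stress(0.18, 133.0, 0.0)
        assert sig[0, 0] == pytest.approx(-23.94, abs=1e-10)
        assert sig[0, 1] == 0.0

    def test_trace_identity(self):
        sig = con.fluid_stress(0.3, 100.0, 50.0)
        assert np.trace(sig) == pytest.approx(-2 * 0.3 * 150.0)

    def test_fraction_bounds(self):
        with pytest.raises(con.ParameterError):
            con.fluid_stress(0.0, 1.0, 0.0)


class TestOsmoticPressure:
    def test_zero_concentration(self):
        assert con.osmotic_pressure(0.0, P) == 0.0

    def test_oxygen_inflow_value(self):
        # c = 0.091 mmol/l at theta = 280 K: Pi = c R theta ~ 211.85 Pa
        assert con.osmotic_pressure(0.091, P) == pytest.approx(211.85, abs=0.01)

    @given(st.floats(1e-6, 1e3))
    @settings(deadline=None, max_examples=30)
    def test_linearity(self, c):
        assert con.osmotic_pressure(2 * c, P) == pytest.approx(
            2 * con.osmotic_pressure(c, P), rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(con.ParameterError):
            con.osmotic_pressure(-1.0, P)


class TestChemicalPotential:
    spec = con.SoluteSpec("FFA", "F", M_mol=0.2825, diffusivity=2e-11)

    def test_reference_concentration(self):
        assert con.chemical_potential(self.spec.c_ref, self.spec, P) == \
            pytest.approx(self.spec.mu0)

    @given(st.floats(1e-8, 1e4))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, c):
        mu = con.chemical_potential(c, self.spec, P)
        back = con.concentration_from_potential(mu, self.spec, P)
        assert back == pytest.approx(c, rel=1e-12)

    def test_strictly_increasing(self):
        cs = np.logspace(-6, 2, 40)
        mus = con.chemical_potential(cs, self.spec, P)
        assert np.all(np.diff(mus) > 0)

    def test_floor_counter(self):
        before = con.chemical_potential_floor_count()
        con.chemical_potential(np.array([0.0, 1.0]), self.spec, P)
        assert con.chemical_potential_floor_count() == before + 1


class TestPermeability:
    def test_isotropic_limit_reproduces_darcy_coefficient(self):
        p0 = P.replace(aniso_weight=0.0)
        K = con.permeability_tensor(P.n0_F, np.array([1.0, 0.0]), p0)
        assert np.allclose(K, p0.darcy_mobility * np.eye(2), rtol=1e-12)

    def test_eigenvalues_decrease_with_fat_crowding(self):
        d = np.array([1.0, 0.0])
        n_fs = np.linspace(0.04, 0.18, 10)
        eig_max = [np.linalg.eigvalsh(con.permeability_tensor(nf, d, P)).max()
                   for nf in n_fs]
        eig_min = [np.linalg.eigvalsh(con.permeability_tensor(nf, d, P)).min()
                   for nf in n_fs]
        assert np.all(np.diff(eig_max) > 0)
        assert np.all(np.diff(eig_min) > 0)
        assert min(eig_min) > 0  # SPD

    def test_frame_covariance(self):
        th = np.deg2rad(90.0)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = np.array([1.0, 0.0])
        K1 = con.permeability_tensor(0.15, d, P)
        K2 = con.permeability_tensor(0.15, Q @ d, P)
        assert np.allclose(K2, Q @ K1 @ Q.T, rtol=1e-12)

    def test_aniso_weight_bound(self):
        with pytest.raises(con.ParameterError):
            con.MaterialParams(aniso_weight=1.0)


class TestSeepage:
    def test_zero_gradient_zero_velocity(self):
        K = con.permeability_tensor(0.18, np.array([1.0, 0.0]), P)
        assert np.allclose(con.seepage_velocity(K, np.zeros(2)), 0.0)

    def test_antiparallel_to_gradient_isotropic(self):
        p0 = P.replace(aniso_weight=0.0)
        K = con.permeability_tensor(0.18, np.array([1.0, 0.0]), p0)
        g = np.array([3.0, -4.0])
        v = con.seepage_velocity(K, g)
        assert np.allclose(v / np.linalg.norm(v), -g / np.linalg.norm(g))

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6),
           st.floats(0.0, 2 * np.pi))
    @settings(deadline=None, max_examples=50)
    def test_darcy_dissipation_nonnegative(self, gx, gy, th):
        d = np.array([np.cos(th), np.sin(th)])
        K = con.permeability_tensor(0.15, d, P)
        assert con.darcy_dissipation(K, np.array([gx, gy])) >= 0.0


class TestSoluteSeepage:
    spec = con.SoluteSpec("FFA", "F", M_mol=0.2825, diffusivity=2e-11)

    def test_zero_inputs_zero_velocity(self):
        v = con.solute_seepage(0.18, np.zeros(2), np.zeros(2), 1.0, self.spec, P)
        assert np.allclose(v, 0.0)

    def test_pure_advection_follows_blood(self):
        w = np.array([2.0e-8, -1.0e-8])
        v = con.solute_seepage(0.18, np.zeros(2), w, 1.0, self.spec, P)
        assert np.allclose(v, self.spec.advect_factor * w)

    def test_diffusion_runs_down_concentration_gradient(self):
        grad_c = np.array([10.0, 0.0])  # mol/m^4
        grad_Pi = grad_c * P.R * P.theta
        v = con.solute_seepage(0.18, grad_Pi, np.zeros(2), 1.0, self.spec, P)
        assert v[0] < 0  # moves toward lower concentration

    def test_fick_diffusivity_recovered(self):
        # flux n_F c w = -n_F D grad c for the diffusive part
        c = 2.0
        grad_c = np.array([5.0, 0.0])
        v = con.solute_seepage(0.18, grad_c * P.R * P.theta, np.zeros(2),
                               c, self.spec, P)
        flux = 0.18 * c * v
        expect = -0.18 * self.spec.diffusivity * grad_c
        assert np.allclose(flux, expect, rtol=1e-12)

    def test_zero_drag_rejected(self):
        bad = con.SoluteSpec("Gy", "S", M_mol=0.1, diffusivity=0.0)
        with pytest.raises(con.ParameterError):
            con.solute_seepage(0.18, np.zeros(2), np.zeros(2), 1.0, bad, P)
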