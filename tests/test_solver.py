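import numpy as np
import pytest

import poroartery as pa
from poroartery import ConvergenceError
from poroartery import kinematics as kin
from poroartery import solver as slv
from poroartery.units import MMHG_TO_MPA, mmhg_to_mpa

from _shooting import shooting_solution
from conftest import PRINTED_LEVELS


class TestResidual:
    def test_stress_free_reference(self, small_model):
        x = slv.reference_guess(small_model)
        res = slv.assemble_residual(x, 0.0, small_model)
        assert np.allclose(res, 0.0, atol=1e-16)

    def test_inadmissible_state_flagged(self, small_model):
        x = slv.reference_guess(small_model)
        x[-2] = x[-1] + 0.1  # a > b collapses the mesh
        res = slv.assemble_residual(x, 0.0, small_model)
        assert not np.all(np.isfinite(res))

    def test_complex_step_matches_fd_jacobian(self, small_model, cfg):
        sol = pa.pressure_sweep(small_model, [40.0], cfg.solver_options())[-1]
        x, dp = sol.x, mmhg_to_mpa(40.0)
        Jcs = slv.jacobian(x, dp, small_model)
        n = x.size
        Jfd = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(x[j]), 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            Jfd[:, j] = (
                slv.assemble_residual(xp, dp, small_model)
                - slv.assemble_residual(xm, dp, small_model)
            ) / (2 * h)
        for j in range(n):  # columnwise agreement
            denom = np.linalg.norm(Jcs[:, j])
            assert np.linalg.norm(Jcs[:, j] - Jfd[:, j]) <= 1e-5 * max(denom, 1e-12)


class TestSolveAtPressure:
    def test_zero_pressure_trivial(self, small_model):
        sol = pa.solve_at_pressure(0.0, small_model)
        assert np.allclose(sol.us, 0.0, atol=1e-14)
        assert sol.Q == pytest.approx(0.0, abs=1e-16)
        assert sol.a == pytest.approx(small_model.ref.a0, abs=1e-14)
        assert sol.b == pytest.approx(small_model.ref.b0, abs=1e-14)

    def test_small_pressure_linearity(self, small_model):
        s1 = pa.solve_at_pressure(0.1, small_model)
        s2 = pa.solve_at_pressure(0.2, small_model)
        assert np.allclose(2.0 * s1.us[1:], s2.us[1:], rtol=1e-2)
        assert 2.0 * s1.Q == pytest.approx(s2.Q, rel=1e-2)

    def test_nonconvergence_reports_pressure(self, small_model, cfg):
        opts = slv.SolverOptions(max_iter=1)
        with pytest.raises(ConvergenceError) as exc:
            pa.solve_at_pressure(160.0, small_model, options=opts)
        assert exc.value.dp_mmhg == 160.0


@pytest.fixture(scope="module")
def sol80(cfg):
    ref = kin.ReferenceConfig(N=50)
    model = slv.Model(
        ref=ref, fung=cfg.fung(), vol=cfg.volumetric(), perm=cfg.permeability()
    )
    return pa.pressure_sweep(model, [80.0], cfg.solver_options())[-1]


class TestConvergedSolution:
    def test_effective_traction_free_surfaces(self, sol80):
        # consistent (reaction-recovered) boundary traction vanishes
        ta, tb = pa.boundary_effective_traction(sol80)
        scale = np.max(np.abs(sol80.sigma_t_eff))
        assert abs(ta) < 1e-8 * scale
        assert abs(tb) < 1e-8 * scale
        # pointwise constitutive recovery at the surface nodes is O(h) small
        assert abs(sol80.sigma_r_eff[0]) < 0.05 * scale
        assert abs(sol80.sigma_r_eff[-1]) < 0.05 * scale

    def test_pore_pressure_boundary_values(self, sol80):
        assert sol80.p[-1] == 0.0
        dp_kpa = 80.0 * MMHG_TO_MPA * 1e3
        assert sol80.p[0] == pytest.approx(dp_kpa, rel=1e-6)
        assert np.all(np.diff(sol80.p) < 0.0)  # monotone decreasing outward

    def test_total_inner_radial_stress_balances_pressure(self, sol80):
        # sigma_r(a) = sigma'_r(a) - p(a) = -dp
        ta, _ = pa.boundary_effective_traction(sol80)
        total = ta - sol80.p[0]
        assert total == pytest.approx(-80.0 * MMHG_TO_MPA * 1e3, rel=1e-6)

    def test_darcy_sign_and_mass_conservation(self, sol80):
        assert sol80.Q > 0.0
        flux = sol80.phi_f * sol80.v_f * 2.0 * np.pi * sol80.r
        assert np.allclose(flux, sol80.Q, rtol=1e-14)

    def test_geometric_constraints(self, sol80):
        assert sol80.us[0] == pytest.approx(sol80.a - sol80.model.ref.a0, abs=1e-12)
        assert sol80.us[-1] == pytest.approx(sol80.b - sol80.model.ref.b0, abs=1e-12)


class TestPressureSweep:
    def test_reference_only_schedule(self, small_model):
        sols = pa.pressure_sweep(small_model, [0.0])
        assert len(sols) == 1 and sols[0].dp_mmhg == 0.0

    def test_radial_stretch_tensile_everywhere(self, fine_sweep):
        # lambda_r stays above one at every printed pressure level
        for sol in fine_sweep:
            if sol.dp_mmhg in PRINTED_LEVELS:
                assert np.all(sol.lam_r > 1.0)

    def test_circumferential_stretch_monotone_in_pressure(self, fine_sweep):
        # at matching normalized positions lambda_theta grows with dp
        printed = [s for s in fine_sweep if s.dp_mmhg in PRINTED_LEVELS]
        for lo, hi in zip(printed[:-1], printed[1:]):
            assert np.all(hi.lam_t > lo.lam_t)

    def test_mesh_convergence_second_order(self, cfg):
        vals = []
        for N in (25, 50, 100, 200):
            ref = kin.ReferenceConfig(N=N)
            model = slv.Model(
                ref=ref, fung=cfg.fung(), vol=cfg.volumetric(), perm=cfg.permeability()
            )
            sols = pa.pressure_sweep(model, [15.0, 80.0], cfg.solver_options())
            vals.append(pa.apparent_measures(sols).J_app[-1])
        d = np.diff(np.array(vals))
        orders = np.log2(np.abs(d[:-1] / d[1:]))
        assert np.all((orders > 1.5) & (orders < 2.5)), orders


class TestStrongFormOracle:
    def test_matches_shooting_solver(self, cfg):
        # independent Lagrangian shooting BVP solve at dp = 80 mmHg
        ref = kin.ReferenceConfig(N=200)
        model = slv.Model(
            ref=ref, fung=cfg.fung(), vol=cfg.volumetric(), perm=cfg.permeability()
        )
        fem = pa.pressure_sweep(model, [80.0], cfg.solver_options())[-1]
        a, b, Q, dense = shooting_solution(model, 80.0)
        assert fem.a == pytest.approx(a, rel=1e-6)
        assert fem.b == pytest.approx(b, rel=1e-6)
        assert fem.Q == pytest.approx(Q, rel=1e-6)
        # displacement profile: r(R) from the oracle vs FEM nodal u_s
        Rf = np.linspace(ref.a0, ref.b0, 101)
        r_oracle = dense.sol(Rf)[0]
        us_oracle = np.interp(fem.r, r_oracle, r_oracle - Rf)
        assert np.allclose(fem.us, us_oracle, atol=1e-6 * np.max(np.abs(fem.us)))
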