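from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from poroartery import ConfigError
from poroartery import analysis as ana


def fake_sweep(radii):
    """Minimal stand-ins for Solutions: (dp, a, b) triples."""
    return [SimpleNamespace(dp_mmhg=dp, a=a, b=b) for dp, a, b in radii]


class TestApparentMeasures:
    def test_self_reference(self):
        am = ana.apparent_measures(fake_sweep([(15.0, 0.34, 0.455)]))
        assert am.at(15.0) == (1.0, 1.0, 1.0)

    def test_similarity_scaling(self):
        s = 1.25
        am = ana.apparent_measures(
            fake_sweep([(15.0, 0.34, 0.455), (80.0, 0.34 * s, 0.455 * s)])
        )
        Lr, Lt, Japp = am.at(80.0)
        assert Lr == pytest.approx(s, rel=1e-14)
        assert Lt == pytest.approx(s, rel=1e-14)
        assert Japp == pytest.approx(s**2, rel=1e-14)

    def test_volume_ratio_identity(self):
        # difference of squares: J_app = Lambda_r * Lambda_theta exactly
        rng = np.random.default_rng(3)
        radii = [(15.0, 0.34, 0.455)] + [
            (float(dp), 0.3 + 0.2 * rng.random(), 0.6 + 0.2 * rng.random())
            for dp in (40, 80, 120, 160)
        ]
        am = ana.apparent_measures(fake_sweep(radii))
        assert np.allclose(am.J_app, am.Lambda_r * am.Lambda_theta, rtol=0, atol=1e-15)

    def test_missing_reference_pressure(self):
        with pytest.raises(ConfigError):
            ana.apparent_measures(fake_sweep([(40.0, 0.38, 0.51)]))


def exp_frame(values):
    return pd.DataFrame(
        [
            {
                "dp_mmHg": dp,
                "lambda_r_apparent": lr,
                "lambda_theta_apparent": lt,
                "j_apparent": lr * lt,
            }
            for dp, (lr, lt) in values.items()
        ]
    )


class TestErrorMeasure:
    EXP = exp_frame({40: (1.05, 1.12), 80: (1.04, 1.27), 120: (1.02, 1.39), 160: (0.99, 1.48)})

    def sim_from_frame(self, df, factor=1.0):
        return ana.ApparentMeasures(
            pressures=df["dp_mmHg"].to_numpy(float),
            Lambda_r=df["lambda_r_apparent"].to_numpy() * factor,
            Lambda_theta=df["lambda_theta_apparent"].to_numpy() * factor,
            J_app=df["j_apparent"].to_numpy() * factor,
            a_bar=0.34,
            b_bar=0.455,
        )

    def test_identity_comparison(self):
        rep = ana.error_measure(self.sim_from_frame(self.EXP), self.EXP)
        assert rep.E_tot == 0.0

    def test_uniform_offset(self):
        rep = ana.error_measure(self.sim_from_frame(self.EXP, factor=1.1), self.EXP)
        for E in (rep.E_Lambda_r, rep.E_Lambda_theta, rep.E_J):
            assert E == pytest.approx(10.0, rel=1e-12)
        assert rep.E_tot == pytest.approx(30.0, rel=1e-12)

    def test_mixed_sign_hand_example(self):
        # deviations +2%, -1%, +3%, -4% average to 2.5% under the L1 measure
        devs = {40: 1.02, 80: 0.99, 120: 1.03, 160: 0.96}
        sim = ana.ApparentMeasures(
            pressures=np.array([40.0, 80.0, 120.0, 160.0]),
            Lambda_r=np.array(
                [self.EXP.iloc[i]["lambda_r_apparent"] * f for i, f in enumerate(devs.values())]
            ),
            Lambda_theta=np.array(
                [self.EXP.iloc[i]["lambda_theta_apparent"] * f for i, f in enumerate(devs.values())]
            ),
            J_app=np.array(
                [self.EXP.iloc[i]["j_apparent"] * f for i, f in enumerate(devs.values())]
            ),
            a_bar=0.34,
            b_bar=0.455,
        )
        rep = ana.error_measure(sim, self.EXP)
        assert rep.E_Lambda_r == pytest.approx(2.5, rel=1e-12)
        assert rep.E_tot == pytest.approx(7.5, rel=1e-12)

    def test_order_invariance(self):
        shuffled = self.EXP.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        a = ana.error_measure(self.sim_from_frame(self.EXP, 1.07), self.EXP)
        b = ana.error_measure(self.sim_from_frame(self.EXP, 1.07), shuffled)
        assert a.E_tot == pytest.approx(b.E_tot, rel=1e-14)

    def test_zero_experimental_value_guard(self):
        bad = self.EXP.copy()
        bad.loc[0, "j_apparent"] = 0.0
        with pytest.raises(ConfigError):
            ana.error_measure(self.sim_from_frame(self.EXP), bad)


class TestGrid:
    def test_axis_counts(self):
        axes = ana.grid_axes()
        assert [len(v) for v in axes.values()] == [29, 46, 30, 41]
        assert axes["C_kPa"][0] == 20.0 and axes["C_kPa"][-1] == 300.0
        assert axes["Kv_kPa"][0] == 5.0 and axes["Kv_kPa"][-1] == 50.0
        assert axes["beta"][0] == pytest.approx(0.1) and axes["beta"][-1] == pytest.approx(3.0)
        assert axes["gamma"][0] == 2.0 and axes["gamma"][-1] == pytest.approx(10.0)

    def test_endpoint_stride(self):
        axes = ana.grid_axes(stride=(28, 45, 29, 40))
        assert ana.grid_size(axes) == 16

    def test_ranking_tiebreak_deterministic(self):
        table = pd.DataFrame(
            {
                "C_kPa": [210.0, 20.0, 20.0],
                "Kv_kPa": [9.0, 9.0, 5.0],
                "beta": [1.5] * 3,
                "gamma": [4.8] * 3,
                "E_Lambda_r": [1.0] * 3,
                "E_Lambda_theta": [1.0] * 3,
                "E_J": [1.0] * 3,
                "E_tot": [3.0, 3.0, 3.0],
                "converged": [True] * 3,
            }
        )
        result = ana.SweepResult(table=table)
        best = result.best_fit
        assert (best["C_kPa"], best["Kv_kPa"]) == (20.0, 5.0)
        assert len(result.top_subset) == 1  # floor(0.01 * 3) -> minimum of 1


class TestPreStretchScan:
    def test_zero_gradient_matches_no_prestretch(self, cfg, small_model):
        import poroartery as pa

        scan = ana.prestretch_scan(
            small_model, 1, [0.0, 0.01, 0.02], 40.0, cfg.solver_options()
        )
        baseline = pa.pressure_sweep(small_model, [40.0], cfg.solver_options())[-1]
        assert scan.table.iloc[0]["E_var_kPa"] == pytest.approx(
            ana.evar_kpa(baseline), rel=1e-9
        )

    def test_select_minimum_interior(self):
        table = pd.DataFrame(
            {"g": np.linspace(0, 0.1, 11),
             "E_var_kPa": [9, 7, 5, 4, 3.5, 3.8, 3.2, 3.9, 5, 7, 9],
             "converged": [True] * 11}
        )
        scan = ana.PreStretchScan(case=1, dp_eval_mmhg=100.0, table=table)
        g, e = ana.select_minimum(scan)
        assert e == 3.2 and g == pytest.approx(0.06)

    def test_select_minimum_requires_interior(self):
        table = pd.DataFrame(
            {"g": np.linspace(0, 0.1, 5),
             "E_var_kPa": [9, 7, 5, 4, 3.5],
             "converged": [True] * 5}
        )
        scan = ana.PreStretchScan(case=1, dp_eval_mmhg=100.0, table=table)
        with pytest.raises(ConfigError):
            ana.select_minimum(scan)
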