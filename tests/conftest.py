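import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poroartery as pa
from poroartery import analysis as ana
from poroartery import kinematics as kin
from poroartery import solver as slv

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

#: pressure levels printed in the result figures [mmHg]
PRINTED_LEVELS = (15.0, 40.0, 80.0, 100.0, 120.0, 160.0)


@pytest.fixture(scope="session")
def cfg():
    return pa.default_config()


@pytest.fixture(scope="session")
def bestfit_model(cfg):
    """Best-fit parameters, baseline geometry, N = 100, no pre-stretch."""
    return cfg.model()


@pytest.fixture(scope="session")
def small_model(cfg):
    """Same parameters on a coarse N = 25 mesh for cheap solver tests."""
    ref = kin.ReferenceConfig(N=25)
    return slv.Model(
        ref=ref, fung=cfg.fung(), vol=cfg.volumetric(), perm=cfg.permeability()
    )


@pytest.fixture(scope="session")
def fine_sweep(cfg, bestfit_model):
    """Continuation sweep on the 5-mmHg grid 0..160 mmHg at N = 100."""
    grid = np.arange(0.0, 160.0 + 2.5, 5.0)
    return pa.pressure_sweep(bestfit_model, grid, cfg.solver_options())


@pytest.fixture(scope="session")
def prestretch_scans(cfg, bestfit_model):
    """Coarse (step 1e-3) E_var scans and refined minima for both cases."""
    g_values = np.arange(0.0, 0.1501, 1.0e-3)
    out = {}
    for case in (1, 2):
        scan = ana.prestretch_scan(
            bestfit_model, case, g_values, 100.0, cfg.solver_options()
        )
        g_min, e_min = ana.refine_minimum(bestfit_model, scan, cfg.solver_options())
        out[case] = (scan, g_min, e_min)
    return out


@pytest.fixture(scope="session")
def prestretch_sweeps(cfg, bestfit_model, prestretch_scans):
    """5-mmHg pressure sweeps at the homogenizing gradient of each case."""
    grid = np.arange(15.0, 160.0 + 2.5, 5.0)
    out = {}
    for case, (_, g_min, _) in prestretch_scans.items():
        model = bestfit_model.with_prestretch(g=g_min, case=case)
        out[case] = pa.pressure_sweep(model, grid, cfg.solver_options())
    return out


@pytest.fixture(scope="session")
def recovery_grid():
    """Well-separated 2^4 parameter grid containing the generating set."""
    return {
        "C_kPa": np.array([150.0, 210.0]),
        "Kv_kPa": np.array([9.0, 20.0]),
        "beta": np.array([0.5, 1.5]),
        "gamma": np.array([3.0, 4.8]),
    }


@pytest.fixture(scope="session")
def recovery_noise_free(recovery_grid, cfg):
    """On-grid, noise-free parameter recovery at desk scale (N = 25)."""
    ref = kin.ReferenceConfig(N=25)
    spec = pa.PseudoExperimentSpec(noise_cv=0.0, seed=123)
    return pa.recovery_experiment(
        spec, recovery_grid, ref, cfg.permeability(), cfg.solver_options()
    )


def peak_sigma_r(sol):
    """Interior peak of the radial effective stress [kPa]."""
    return float(np.max(sol.sigma_r_eff[1:-1]))
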