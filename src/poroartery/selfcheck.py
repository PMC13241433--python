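"""Quick built-in verification suite (`poroartery verify`).

Runs a handful of fast oracle and property checks at reduced mesh size:
kinematic identities, finite-difference agreement of the closed-form
stress, Kozeny-Carman reference consistency, and boundary/constraint
satisfaction of a converged solve.  The full oracle suite lives in the
package's pytest tests; this is a smoke-level field check.
"""

from __future__ import annotations

import numpy as np

from . import analysis as ana
from . import constitutive as cst
from . import solver as slv
from .config import RunConfig
from .units import mmhg_to_mpa


def run_selfcheck(cfg: RunConfig | None = None) -> list[tuple[str, bool, str]]:
    cfg = cfg or RunConfig(N=40)
    results = []

    def check(name, ok, detail=""):
        results.append((name, bool(ok), detail))

    fung, vol = cfg.fung(), cfg.volumetric()

    # energy minimum at identity
    W0 = float(cst.strain_energy(fung, vol, 1.0, 1.0))
    s0 = cst.effective_stress(fung, vol, 1.0, 1.0)
    check("W(1,1) = 0 and stress-free identity",
          W0 == 0.0 and abs(float(s0[0])) < 1e-15 and abs(float(s0[1])) < 1e-15,
          f"W={W0:.3e}")

    # closed-form stress vs central finite differences
    rng = np.random.default_rng(7)
    ok, worst = True, 0.0
    for lr, lt in rng.uniform(0.8, 1.6, size=(20, 2)):
        sr, st = (float(v) for v in cst.effective_stress(fung, vol, lr, lt))
        eps = 1e-6
        dWr = (cst.strain_energy(fung, vol, lr + eps, lt)
               - cst.strain_energy(fung, vol, lr - eps, lt)) / (2 * eps)
        dWt = (cst.strain_energy(fung, vol, lr, lt + eps)
               - cst.strain_energy(fung, vol, lr, lt - eps)) / (2 * eps)
        J = lr * lt
        for got, fd, lam in ((sr, dWr, lr), (st, dWt, lt)):
            rel = abs(got - lam / J * fd) / max(abs(got), 1e-9)
            worst = max(worst, rel)
            ok &= rel < 1e-5
    check("stress matches FD oracle (rel 1e-5)", ok, f"worst rel {worst:.2e}")

    # Kozeny-Carman normalization
    perm = cfg.permeability()
    k_ref = float(cst.permeability(perm, perm.phi_f0))
    check("k(phi_f0) = k0", abs(k_ref - perm.k0) < 1e-18, f"k={k_ref:.4g}")

    # converged solve at 80 mmHg: constraints and Darcy sign
    model = cfg.model()
    try:
        sols = slv.pressure_sweep(model, [15.0, 80.0], cfg.solver_options())
    except Exception as exc:  # pragma: no cover - reported, not raised
        check("forward solve at 80 mmHg", False, repr(exc))
        return results
    sol = sols[-1]
    res = slv.assemble_residual(sol.x, mmhg_to_mpa(80.0), model)
    ta, tb = slv.boundary_effective_traction(sol)
    check("converged residual below tolerance",
          float(np.linalg.norm(res)) < 1e-9, f"||res||={np.linalg.norm(res):.2e}")
    check("effective traction-free surfaces",
          abs(ta) < 1e-6 and abs(tb) < 1e-6, f"({ta:.2e}, {tb:.2e}) kPa")
    check("outward flow under positive dp", sol.Q > 0.0, f"Q={sol.Q:.3e}")
    p = sol.p
    check("pore pressure: p(b)=0, p(a)=dp",
          abs(p[-1]) < 1e-12 and abs(p[0] - 80.0 * 0.133322) / (80.0 * 0.133322) < 1e-6,
          f"p(a)={p[0]:.6g} kPa")

    # apparent-measure identity
    am = ana.apparent_measures(sols)
    check("J_app = Lambda_r * Lambda_theta",
          np.allclose(am.J_app, am.Lambda_r * am.Lambda_theta, rtol=0, atol=1e-14))

    # saturation at the solution
    check("saturation phi_s + phi_f = 1",
          np.allclose(sol.phi_f + (1.0 - sol.phi_f), 1.0, atol=1e-15))
    return results
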