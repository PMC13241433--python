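"""Independent strong-form oracle: Lagrangian shooting solver.

Integrates the radial momentum balance as an ODE in the reference
coordinate R from a0 to b0, with state (r, sigma'_r, p):

    dr/dR        = lambda_e_r       (lambda_r / lambda_p_r)
    dsigma'_r/dR = [(sigma'_theta - sigma'_r)/r - Q/(2 pi k r)] dr/dR
    dp/dR        = -Q/(2 pi k r) dr/dR

At each step lambda_e_theta = r/R is known and lambda_r is recovered by a
bracketed scalar root solve of sigma'_r(lambda_r, lambda_theta) = s.  The
two shooting unknowns (a, Q) are determined by sigma'_r(b0) = 0 and
p(b0) = 0 via scipy.optimize.root.  This shares no discretization machinery
with the Galerkin solver.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from poroartery import constitutive as cst
from poroartery.units import mmhg_to_mpa


def shooting_solution(model, dp_mmhg, rtol=1.0e-11, atol=1.0e-13):
    """Solve the inflation BVP by shooting; returns (a, b, Q, dense_sol)."""
    ref, fung, vol, perm = model.ref, model.fung, model.vol, model.perm
    ps = model.prestretch
    dp = mmhg_to_mpa(dp_mmhg)

    def prestretch(R):
        if ps is None or ps.is_identity:
            return 1.0, 1.0
        lpt = float(ps.lambda_p_theta(R))
        return (1.0 / lpt if ps.case == 2 else 1.0), lpt

    def rhs(R, y, Q):
        r, s, _ = y
        lpr, lpt = prestretch(R)
        lam_t = (r / R) * lpt
        lam_r = brentq(
            lambda x: float(cst.effective_stress(fung, vol, x, lam_t)[0]) - s,
            0.1, 10.0, xtol=1.0e-14,
        )
        st = float(cst.effective_stress(fung, vol, lam_r, lam_t)[1])
        lam_er = lam_r / lpr
        lam_et = r / R
        phi = 1.0 - (1.0 - ref.phi_f0) / (lam_er * lam_et)
        k = float(cst.permeability(perm, phi))
        darcy = Q / (2.0 * np.pi * k * r)
        return [lam_er, ((st - s) / r - darcy) * lam_er, -darcy * lam_er]

    def integrate(a, Q, dense=False):
        return solve_ivp(
            rhs, (ref.a0, ref.b0), [a, 0.0, dp], args=(Q,),
            rtol=rtol, atol=atol, dense_output=dense,
        )

    def objective(z):
        sol = integrate(*z)
        return [sol.y[1, -1], sol.y[2, -1]]

    a_guess = ref.a0 * (1.0 + 0.15 * dp_mmhg / 80.0)
    q_guess = dp * 2.0 * np.pi * perm.k0 * 0.5 * (ref.a0 + ref.b0) / ref.thickness
    res = root(objective, [a_guess, q_guess], tol=1.0e-13)
    assert res.success, res.message
    a, Q = res.x
    sol = integrate(a, Q, dense=True)
    return float(a), float(sol.y[0, -1]), float(Q), sol
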