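"""Coupled solid-fluid solver for steady inflation of the biphasic wall.

Strong form (radial momentum of the mixture with Darcy's law substituted):

    d sigma'_r/dr + (sigma'_r - sigma'_theta)/r + Q/(2 pi k r) = 0,
    r in [a, b],

with zero *effective* traction at both surfaces (the skeleton is
mechanically unconstrained there; the transmural pressure acts entirely on
the pore fluid).  The Galerkin weak form on N two-node elements of equal
length reads, for every hat function w,

    int_a^b ( sigma'_r r dw/dr + w sigma'_theta - Q w / (2 pi k) ) dr = 0,

and is closed by the pressure-drop constraint

    dp = (Q / 2 pi) int_a^b dr / (k r)

and the geometric constraints u_s(a) = a - a0, u_s(b) = b - b0.

Unknown vector x = (u_s at the N+1 nodes, Q, a, b).  The mesh lives on
fixed normalized coordinates xi in [0, 1] with r = a + (b - a) xi, so the
weak-form integrals differentiate through the moving domain.  The Newton
tangent is evaluated by complex-step differentiation of the residual
(exact to machine precision; the assembly is complex-analytic), with a
backtracking line search on the residual norm; inadmissible states yield a
non-finite residual and are rejected by the search.  Pressure is applied by
warm-started continuation with adaptive step halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constitutive as cst
from . import kinematics as kin
from .errors import ConvergenceError
from .units import mmhg_to_mpa, mpa_to_kpa

__all__ = [
    "Model",
    "SolverOptions",
    "Solution",
    "assemble_residual",
    "jacobian",
    "solve_at_pressure",
    "pressure_sweep",
    "recover_pore_pressure",
    "boundary_effective_traction",
]

_GAUSS_ETA = np.array([0.5 - 0.5 / math.sqrt(3.0), 0.5 + 0.5 / math.sqrt(3.0)])
_CS_STEP = 1.0e-30


@dataclass(frozen=True)
class Model:
    """Geometry + constitutive parameter bundle defining one forward problem."""

    ref: kin.ReferenceConfig
    fung: cst.FungParams
    vol: cst.VolumetricParams
    perm: cst.PermeabilityParams
    prestretch: kin.PreStretchField | None = None

    def with_prestretch(self, g: float, case: int) -> "Model":
        return replace(
            self, prestretch=kin.PreStretchField(ref=self.ref, g=g, case=case)
        )

    @property
    def n_unknowns(self) -> int:
        return self.ref.N + 4


@dataclass(frozen=True)
class SolverOptions:
    newton_rtol: float = 1.0e-10
    newton_atol: float = 1.0e-12
    max_iter: int = 50
    max_backtracks: int = 40
    dp_step_mmhg: float = 5.0
    min_dp_step_mmhg: float = 0.15625


def reference_guess(model: Model) -> np.ndarray:
    """Initial unknown vector: undeformed skeleton, no flow."""
    x = np.zeros(model.n_unknowns)
    x[-2] = model.ref.a0
    x[-1] = model.ref.b0
    return x


def _gauss_fields(x, model: Model):
    """Kinematic and constitutive fields at the 2 Gauss points per element.

    ``x`` has shape (..., N+4); every returned array broadcasts to
    (..., N, 2).  Returns (r, us, lam_r, lam_t, phi_f, k, bad) where ``bad``
    is a boolean mask over the leading batch shape flagging inadmissible
    states.
    """
    N = model.ref.N
    us_nodes = x[..., : N + 1]
    a = x[..., N + 1 + 1]
    b = x[..., N + 1 + 2]
    h = (b - a) / N

    xi_left = (np.arange(N) / N)[:, None]
    xi_g = xi_left + _GAUSS_ETA[None, :] / N  # (N, 2)
    r = a[..., None, None] + (b - a)[..., None, None] * xi_g
    usL = us_nodes[..., :-1, None]
    usR = us_nodes[..., 1:, None]
    us = usL * (1.0 - _GAUSS_ETA) + usR * _GAUSS_ETA
    dus = (usR - usL) / h[..., None, None]

    den_r = 1.0 - dus
    den_t = 1.0 - us / r
    bad = (
        (np.real(a) <= 0.0)
        | (np.real(h) <= 0.0)
        | np.any(np.real(den_r) <= 1.0e-9, axis=(-2, -1))
        | np.any(np.real(den_t) <= 1.0e-9, axis=(-2, -1))
    )

    with np.errstate(all="ignore"):
        lam_er, lam_et = kin.elastic_stretches_from_grad(us, dus, r)
        if model.prestretch is None or model.prestretch.is_identity:
            lam_r, lam_t = lam_er, lam_et
        else:
            R = r - us
            ps = model.prestretch
            lam_pt = 1.0 + ps.g * (R - model.ref.mid_radius) / model.ref.thickness
            lam_pr = 1.0 / lam_pt if ps.case == 2 else 1.0
            lam_r = lam_er * lam_pr
            lam_t = lam_et * lam_pt
        Je = lam_er * lam_et
        phi_f = 1.0 - (1.0 - model.ref.phi_f0) / Je
        k = cst.permeability(model.perm, phi_f, check=False)

    bad = bad | np.any(
        (np.real(phi_f) <= 1.0e-9) | (np.real(phi_f) >= 1.0 - 1.0e-9), axis=(-2, -1)
    )
    return r, us, lam_r, lam_t, phi_f, k, bad, h


def assemble_residual(x, dp_mpa: float, model: Model):
    """Residual of the discrete system; shape (..., N+4) for x (..., N+4).

    Inadmissible batch entries (kinematic denominators or porosity out of
    range, collapsed mesh) return +inf rows so the line search rejects them.
    """
    x = np.asarray(x)
    N = model.ref.N
    r, us, lam_r, lam_t, phi_f, k, bad, h = _gauss_fields(x, model)
    Q = x[..., N + 1]
    a = x[..., N + 2]
    b = x[..., N + 3]

    with np.errstate(all="ignore"):
        sig_r, sig_t = cst.effective_stress(model.fung, model.vol, lam_r, lam_t)
        darcy = Q[..., None, None] / (2.0 * np.pi * k)
        A = sig_r * r  # multiplies dw/dr = -/+ 1/h
        B = sig_t - darcy  # multiplies w
        half_h = 0.5 * h[..., None, None]
        contrib_L = (-0.5) * A + half_h * (1.0 - _GAUSS_ETA) * B
        contrib_R = (+0.5) * A + half_h * _GAUSS_ETA * B

        res = np.zeros(x.shape, dtype=x.dtype)
        res[..., :N] += contrib_L.sum(axis=-1)
        res[..., 1 : N + 1] += contrib_R.sum(axis=-1)

        # pressure-drop constraint: dp - (Q/2pi) int dr/(k r)
        integ = (half_h / (k * r)).sum(axis=(-2, -1))
        res[..., N + 1] = dp_mpa - Q / (2.0 * np.pi) * integ
        # geometric constraints
        res[..., N + 2] = x[..., 0] - (a - model.ref.a0)
        res[..., N + 3] = x[..., N] - (b - model.ref.b0)

    if np.any(bad):
        res = np.where(bad[..., None], np.inf, res)
    return res


def jacobian(x: np.ndarray, dp_mpa: float, model: Model, chunk: int = 64):
    """Complex-step Jacobian of the residual at a real admissible state x.

    Exact to machine precision (step 1e-30); the assembly is analytic in the
    unknowns, so no subtractive cancellation occurs.
    """
    n = x.size
    J = np.empty((n, n))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        X = np.tile(x.astype(complex), (hi - lo, 1))
        X[np.arange(hi - lo), np.arange(lo, hi)] += 1j * _CS_STEP
        R = assemble_residual(X, dp_mpa, model)
        J[:, lo:hi] = R.imag.T / _CS_STEP
    return J


@dataclass
class Solution:
    """Converged state at one transmural pressure, with nodal profiles.

    Stress profiles are reported in kPa, radii/displacements in mm, the pore
    pressure in kPa and the fluid velocity in mm/s.  Nodal stretches use
    averaged adjacent-element displacement gradients (one-sided at the two
    surface nodes).
    """

    dp_mmhg: float
    x: np.ndarray
    model: Model
    iterations: int
    residual_norm: float

    r: np.ndarray = field(init=False)
    us: np.ndarray = field(init=False)
    lam_r: np.ndarray = field(init=False)
    lam_t: np.ndarray = field(init=False)
    J: np.ndarray = field(init=False)
    phi_f: np.ndarray = field(init=False)
    k: np.ndarray = field(init=False)
    sigma_r_eff: np.ndarray = field(init=False)
    sigma_t_eff: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)
    v_f: np.ndarray = field(init=False)

    def __post_init__(self):
        m = self.model
        N = m.ref.N
        self.us = self.x[: N + 1].copy()
        mesh = kin.RadialMesh(a=self.a, b=self.b, N=N)
        fld = kin.DisplacementField(mesh, self.us)
        self.r = mesh.r_nodes
        dus = fld.nodal_gradient()
        lam_e = kin.elastic_stretches_from_grad(self.us, dus, self.r)
        state = kin.total_state(
            lam_e, m.prestretch, self.r - self.us, m.ref.phi_f0
        )
        self.lam_r = state.lam_r
        self.lam_t = state.lam_t
        self.J = state.J
        self.phi_f = state.phi_f
        self.k = cst.permeability(m.perm, state.phi_f)
        sr, st = cst.effective_stress(m.fung, m.vol, state.lam_r, state.lam_t)
        self.sigma_r_eff = mpa_to_kpa(sr)
        self.sigma_t_eff = mpa_to_kpa(st)
        self.p = mpa_to_kpa(recover_pore_pressure(self.x, m))
        self.v_f = kin.fluid_velocity(self.Q, state.phi_f, self.r)

    @property
    def Q(self) -> float:
        return float(self.x[self.model.ref.N + 1])

    @property
    def a(self) -> float:
        return float(self.x[self.model.ref.N + 2])

    @property
    def b(self) -> float:
        return float(self.x[self.model.ref.N + 3])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_mm": self.r,
                "us_mm": self.us,
                "lambda_r": self.lam_r,
                "lambda_theta": self.lam_t,
                "J": self.J,
                "phi_f": self.phi_f,
                "k": self.k,
                "sigma_r_eff_kPa": self.sigma_r_eff,
                "sigma_theta_eff_kPa": self.sigma_t_eff,
                "p_kPa": self.p,
                "v_f_mm_s": self.v_f,
            }
        )


def recover_pore_pressure(x: np.ndarray, model: Model) -> np.ndarray:
    """Nodal pore pressure p(r) = (Q/2pi) int_r^b dr'/(k r') [MPa].

    Uses the same per-element 2-point Gauss quadrature as the pressure-drop
    constraint, so p(a) reproduces the applied dp to solver tolerance and
    p(b) = 0 by construction.
    """
    N = model.ref.N
    Q = x[N + 1]
    r, _, _, _, _, k, _, h = _gauss_fields(x, model)
    elem = (0.5 * h / (k * r)).sum(axis=-1)  # (N,)
    p = np.zeros(N + 1)
    p[:-1] = Q / (2.0 * np.pi) * np.cumsum(elem[::-1])[::-1]
    return p


def boundary_effective_traction(sol: Solution) -> tuple[float, float]:
    """Consistently recovered effective radial traction at the two surfaces.

    The weak-form equation of each boundary node equals -a*sigma'_r(a)
    (resp. +b*sigma'_r(b)) when the zero-traction assumption is dropped, so
    the recovered tractions are residual_0/(-a) and residual_N/b — the
    discretely consistent reaction.  Returned in kPa.
    """
    res = assemble_residual(sol.x, mmhg_to_mpa(sol.dp_mmhg), sol.model)
    N = sol.model.ref.N
    return (
        mpa_to_kpa(-float(res[0]) / sol.a),
        mpa_to_kpa(float(res[N]) / sol.b),
    )


def _newton(x0, dp_mpa, model, opts: SolverOptions):
    x = np.array(x0, dtype=float)
    res = assemble_residual(x, dp_mpa, model)
    nrm = float(np.linalg.norm(res))
    if not np.isfinite(nrm):
        raise ConvergenceError("initial state inadmissible")
    tol = max(opts.newton_atol, opts.newton_rtol * nrm)
    for it in range(opts.max_iter):
        if nrm < tol:
            return x, it, nrm
        Jm = jacobian(x, dp_mpa, model)
        try:
            delta = np.linalg.solve(Jm, -res)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Jacobian: {exc}") from exc
        alpha = 1.0
        for _ in range(opts.max_backtracks):
            xn = x + alpha * delta
            rn = assemble_residual(xn, dp_mpa, model)
            nn = float(np.linalg.norm(rn))
            if np.isfinite(nn) and (nn < nrm or nn < tol):
                x, res, nrm = xn, rn, nn
                break
            alpha *= 0.5
        else:
            raise ConvergenceError(
                f"line search stalled at ||res|| = {nrm:.3e}"
            )
    if nrm < tol:
        return x, opts.max_iter, nrm
    raise ConvergenceError(
        f"Newton did not converge in {opts.max_iter} iterations "
        f"(||res|| = {nrm:.3e})"
    )


def solve_at_pressure(
    dp_mmhg: float,
    model: Model,
    x0: np.ndarray | None = None,
    options: SolverOptions | None = None,
) -> Solution:
    """Solve the coupled system at one transmural pressure (single Newton).

    ``x0`` warm-starts the iteration; the default is the undeformed
    reference guess, adequate near dp = 0 (use :func:`pressure_sweep` for
    large pressures).
    """
    opts = options or SolverOptions()
    x0 = reference_guess(model) if x0 is None else x0
    try:
        x, it, nrm = _newton(x0, mmhg_to_mpa(dp_mmhg), model, opts)
    except ConvergenceError as exc:
        exc.dp_mmhg = dp_mmhg
        raise
    return Solution(dp_mmhg=dp_mmhg, x=x, model=model, iterations=it, residual_norm=nrm)


def pressure_sweep(
    model: Model,
    schedule_mmhg,
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
) -> list[Solution]:
    """Solve at every pressure in ``schedule_mmhg`` by warm-started
    continuation from 0, with adaptive sub-stepping on Newton failure.

    Returns Solutions in ascending pressure order (one per requested level).
    """
    opts = options or SolverOptions()
    targets = sorted(float(p) for p in schedule_mmhg)
    if targets and targets[0] < 0.0:
        raise ValueError("pressure schedule must be non-negative")
    x = reference_guess(model) if x0 is None else np.array(x0, dtype=float)

    sols: list[Solution] = []
    p_cur = 0.0
    # equilibrate the zero-pressure state (non-trivial with pre-stretch)
    x, it, nrm = _newton(x, 0.0, model, opts)
    if targets and targets[0] == 0.0:
        sols.append(Solution(0.0, x.copy(), model, it, nrm))
        targets = targets[1:]

    step = opts.dp_step_mmhg
    for target in targets:
        while p_cur < target - 1.0e-12:
            p_try = min(p_cur + step, target)
            try:
                x_new, it, nrm = _newton(x, mmhg_to_mpa(p_try), model, opts)
            except ConvergenceError:
                step *= 0.5
                if step < opts.min_dp_step_mmhg:
                    raise ConvergenceError(
                        f"continuation failed near dp = {p_try:g} mmHg",
                        dp_mmhg=p_try,
                    ) from None
                continue
            x, p_cur = x_new, p_try
            step = min(step * 2.0, opts.dp_step_mmhg)
        sols.append(Solution(p_cur, x.copy(), model, it, nrm))
    return sols


def sweep_summary(sols: list[Solution]) -> pd.DataFrame:
    """One-row-per-pressure summary (dp_mmHg, a_mm, b_mm, Q, iterations)."""
    return pd.DataFrame(
        {
            "dp_mmHg": [s.dp_mmhg for s in sols],
            "a_mm": [s.a for s in sols],
            "b_mm": [s.b for s in sols],
            "Q_mm2_s": [s.Q for s in sols],
            "iterations": [s.iterations for s in sols],
            "residual_norm": [s.residual_norm for s in sols],
        }
    )
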