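"""Finite-strain kinematics of the biphasic arterial wall.

The wall occupies the annulus r in [a, b] in the current configuration and
[a0, b0] in the reference configuration.  The solid skeleton is tracked
through its Eulerian radial displacement u_s(r) = r - R(r), where R is the
reference position of the material point now at r.  Under plane strain the
elastic stretches follow directly from u_s,

    lambda_e_r = (1 - du_s/dr)^(-1),    lambda_e_theta = (1 - u_s/r)^(-1),

and a multiplicative pre-stretch F_p = diag(lambda_p_r, lambda_p_theta, 1),
prescribed in the reference configuration, composes with the elastic part to
give the total stretches lambda_m = lambda_e_m * lambda_p_m and the volume
ratio J = lambda_r * lambda_theta.

Because both phases are intrinsically incompressible, macroscopic volume
change happens purely by porosity change: with J_e = lambda_e_r *
lambda_e_theta,

    J_e = (1 - phi_f0) / (1 - phi_f)   =>   phi_f = 1 - (1 - phi_f0) / J_e.

The interstitial fluid moves radially as a steady line source of strength Q
per unit axial length, phi_f * v_f = Q / (2 pi r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDeformationError, PorosityBoundError

__all__ = [
    "ReferenceConfig",
    "RadialMesh",
    "DisplacementField",
    "PreStretchField",
    "KinematicState",
    "elastic_stretches",
    "elastic_stretches_from_grad",
    "total_state",
    "eulerian_fluid_fraction",
    "fluid_velocity",
]

#: smallest admissible value of the kinematic denominators
_DENOM_TINY = 1.0e-12


@dataclass(frozen=True)
class ReferenceConfig:
    """Reference geometry, porosity and mesh resolution.

    Parameters
    ----------
    a0, b0 : float
        Inner and outer radii in the reference (zero transmural pressure)
        configuration [mm].
    phi_f0 : float
        Reference fluid volume fraction (porosity) [-].
    N : int
        Number of two-node line elements of equal length.
    """

    a0: float = 0.31
    b0: float = 0.42
    phi_f0: float = 0.40
    N: int = 100

    def __post_init__(self):
        if not (0.0 < self.a0 < self.b0):
            raise ValueError(f"require 0 < a0 < b0, got a0={self.a0}, b0={self.b0}")
        if not (0.0 < self.phi_f0 < 1.0):
            raise ValueError(f"phi_f0 must lie in (0, 1), got {self.phi_f0}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")

    @property
    def phi_s0(self) -> float:
        """Reference solid volume fraction; saturation phi_s0 + phi_f0 = 1."""
        return 1.0 - self.phi_f0

    @property
    def thickness(self) -> float:
        return self.b0 - self.a0

    @property
    def mid_radius(self) -> float:
        return 0.5 * (self.a0 + self.b0)


@dataclass(frozen=True)
class RadialMesh:
    """Equal-length element mesh of the current annulus [a, b].

    Nodes sit at normalized coordinates xi in [0, 1] with r = a + (b - a) xi,
    so the mesh moves with the (unknown) current radii.
    """

    a: float
    b: float
    N: int

    def __post_init__(self):
        if not (0.0 < self.a < self.b):
            raise ValueError(f"require 0 < a < b, got a={self.a}, b={self.b}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")

    @property
    def xi(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.N + 1)

    @property
    def r_nodes(self) -> np.ndarray:
        return self.a + (self.b - self.a) * self.xi

    @property
    def h(self) -> float:
        """Element length [mm]."""
        return (self.b - self.a) / self.N


@dataclass
class DisplacementField:
    """Piecewise-linear nodal solid displacement on a :class:`RadialMesh`."""

    mesh: RadialMesh
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.N + 1,):
            raise ValueError(
                f"expected {self.mesh.N + 1} nodal values, got {self.values.shape}"
            )

    def _element_index(self, r):
        r = np.asarray(r, dtype=float)
        idx = np.clip(
            np.floor((r - self.mesh.a) / self.mesh.h).astype(int), 0, self.mesh.N - 1
        )
        return r, idx

    def us(self, r):
        """Interpolated displacement u_s(r) [mm]."""
        r, idx = self._element_index(r)
        rn = self.mesh.r_nodes
        t = (r - rn[idx]) / self.mesh.h
        return (1.0 - t) * self.values[idx] + t * self.values[idx + 1]

    def dus_dr(self, r):
        """Element-wise constant gradient du_s/dr at r [-]."""
        r, idx = self._element_index(r)
        return (self.values[idx + 1] - self.values[idx]) / self.mesh.h

    def nodal_gradient(self) -> np.ndarray:
        """Nodal gradient by averaging the two adjacent element gradients.

        End nodes take the one-sided element value (O(h) accurate there).
        """
        g = np.diff(self.values) / self.mesh.h
        out = np.empty(self.mesh.N + 1)
        out[0], out[-1] = g[0], g[-1]
        out[1:-1] = 0.5 * (g[:-1] + g[1:])
        return out


@dataclass(frozen=True)
class PreStretchField:
    """Linear-in-radius circumferential pre-stretch encoding residual stress.

    lambda_p_theta(R) = 1 + g * (R - R_mid) / (b0 - a0), with R_mid the
    mid-wall reference radius, so the mid-wall value is exactly 1 and ``g``
    is the total change of lambda_p_theta across the wall thickness
    (dimensionless, per-thickness convention).  Radial coupling:

    * case 1: lambda_p_r = 1 (weak transverse coupling);
    * case 2: lambda_p_r = 1 / lambda_p_theta (det F_p = 1 pointwise,
      strong transverse coupling).

    Plane strain fixes lambda_p_z = 1.  g = 0 gives the identity pre-stretch.
    """

    ref: ReferenceConfig
    g: float = 0.0
    case: int = 1

    def __post_init__(self):
        if self.case not in (1, 2):
            raise ValueError(f"case must be 1 or 2, got {self.case}")
        # keep lambda_p_theta positive across [a0, b0] with margin
        if not (-1.0 < self.g < 2.0):
            raise ValueError(f"pre-stretch gradient g out of range: {self.g}")

    @property
    def is_identity(self) -> bool:
        return self.g == 0.0

    def lambda_p_theta(self, R):
        return 1.0 + self.g * (R - self.ref.mid_radius) / self.ref.thickness

    def lambda_p_r(self, R):
        lpt = self.lambda_p_theta(R)
        if self.case == 1:
            return np.ones_like(np.asarray(lpt))
        return 1.0 / lpt

    def stretches(self, R):
        """(lambda_p_r, lambda_p_theta) at reference radius R."""
        lpt = self.lambda_p_theta(R)
        if self.case == 1:
            lpr = np.ones_like(np.asarray(lpt))
        else:
            lpr = 1.0 / lpt
        return lpr, lpt


@dataclass(frozen=True)
class KinematicState:
    """Pointwise kinematic state (arrays broadcast over evaluation points)."""

    lam_er: np.ndarray
    lam_et: np.ndarray
    lam_r: np.ndarray
    lam_t: np.ndarray
    J: np.ndarray
    Je: np.ndarray
    phi_f: np.ndarray

    lam_z: float = 1.0

    @property
    def phi_s(self):
        return 1.0 - self.phi_f


def elastic_stretches_from_grad(us, dus, r):
    """Elastic stretches from pointwise (u_s, du_s/dr, r).

    Pure arithmetic, dtype-generic (used with complex arrays inside the
    solver's complex-step Jacobian).  No admissibility check.
    """
    return 1.0 / (1.0 - dus), 1.0 / (1.0 - us / r)


def elastic_stretches(us_field: DisplacementField, r):
    """(lambda_e_r, lambda_e_theta) at radius r, from the element shape
    functions of a piecewise-linear displacement field.

    Raises
    ------
    InvalidDeformationError
        If either denominator 1 - du_s/dr or 1 - u_s/r is non-positive,
        naming the offending radius.
    """
    r = np.asarray(r, dtype=float)
    us = us_field.us(r)
    dus = us_field.dus_dr(r)
    den_r = 1.0 - dus
    den_t = 1.0 - us / r
    bad = (den_r <= _DENOM_TINY) | (den_t <= _DENOM_TINY)
    if np.any(bad):
        r_bad = np.atleast_1d(r)[np.atleast_1d(bad)][0]
        raise InvalidDeformationError(
            f"non-positive kinematic denominator at r = {float(r_bad):.6g} mm"
        )
    return 1.0 / den_r, 1.0 / den_t


def total_state(lam_e, prestretch: PreStretchField | None, R, phi_f0) -> KinematicState:
    """Compose elastic stretches with the pre-stretch at reference radius R.

    Returns the full :class:`KinematicState`, with the fluid fraction from
    the porosity route phi_f = 1 - (1 - phi_f0)/J_e.

    Raises
    ------
    PorosityBoundError
        If phi_f leaves (0, 1).
    """
    lam_er, lam_et = (np.asarray(x) for x in lam_e)
    if prestretch is None or prestretch.is_identity:
        lam_pr = np.ones_like(lam_er)
        lam_pt = np.ones_like(lam_et)
    else:
        lam_pr, lam_pt = prestretch.stretches(np.asarray(R))
    lam_r = lam_er * lam_pr
    lam_t = lam_et * lam_pt
    Je = lam_er * lam_et
    J = lam_r * lam_t
    phi_f = 1.0 - (1.0 - phi_f0) / Je
    if np.any(phi_f <= 0.0) or np.any(phi_f >= 1.0):
        raise PorosityBoundError(
            f"fluid volume fraction out of (0, 1): range "
            f"[{np.min(phi_f):.4g}, {np.max(phi_f):.4g}]"
        )
    return KinematicState(
        lam_er=lam_er, lam_et=lam_et, lam_r=lam_r, lam_t=lam_t, J=J, Je=Je, phi_f=phi_f
    )


def eulerian_fluid_fraction(us_field: DisplacementField, r, phi_f0):
    """Fluid fraction by the Eulerian divergence route,

        (phi_f - phi_f0)/(1 - phi_f0) = (1/r) d/dr ( r u_s - u_s^2 / 2 ),

    with the radial derivative taken numerically (second-order central
    differences of the flux potential on the sampling grid).  This is a
    cross-check against the porosity route of :func:`total_state` and is
    only meaningful without pre-stretch.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ValueError("need a 1-D sampling grid with at least 3 points")
    us = us_field.us(r)
    den_r = 1.0 - us_field.dus_dr(r)
    den_t = 1.0 - us / r
    if np.any(den_r <= _DENOM_TINY) or np.any(den_t <= _DENOM_TINY):
        raise InvalidDeformationError("non-positive kinematic denominator")
    psi = r * us - 0.5 * us**2
    dpsi = np.gradient(psi, r, edge_order=2)
    return phi_f0 + (1.0 - phi_f0) * dpsi / r


def fluid_velocity(Q, phi_f, r):
    """Interstitial fluid velocity v_f = Q / (2 pi r phi_f) [mm/s]."""
    r = np.asarray(r)
    phi_f = np.asarray(phi_f)
    if np.any(np.real(r) <= 0.0):
        raise ValueError("radius must be positive")
    if np.any(np.real(phi_f) <= 0.0):
        raise PorosityBoundError("phi_f must be positive")
    return Q / (2.0 * np.pi * r * phi_f)
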