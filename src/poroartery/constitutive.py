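"""Constitutive behaviour of the solid skeleton and interstitial fluid.

Strain energy W = W_dev + W_vol:

* W_dev is a Fung-type anisotropic exponential,
  W_dev = (C/2) (exp(Qw) - 1) with

      Qw = b1 Et^2 + b2 Ez^2 + b3 Er^2
           + 2 b4 Et Ez + 2 b5 Er Ez + 2 b6 Et Er,

  built from deviatoric Green-Lagrange strains Em = (lm~^2 - 1)/2, where
  lm~ = J^(-1/3) * lambda_m are the isochoric stretches.  Under plane strain
  lambda_z = 1 but lz~ = J^(-1/3) != 1 when J != 1, so the axial terms still
  contribute.

* W_vol penalizes volume change of the porous skeleton (a porosity change,
  both phases being intrinsically incompressible), with a soft nonlinear
  branch in expansion and a stiff log barrier in compression:

      W_vol = Kv (exp(f(J)) - 1),            J >= 1,
              (Kv/2) ((J^2 - 1)/2 - ln J),   J <  1,
      f(J)  = beta (J - 1)^gamma + (J - 1)^2 / 2.

  Both branches vanish at J = 1 with matching first derivative (C^1).

Effective Cauchy stresses follow from sigma'_m = (lambda_m / J) dW/dlambda_m
with lambda_z = 1 held fixed and J = lambda_r * lambda_theta differentiated
through.  The derivative is hand-derived in closed form (finite differences
are used only as an independent oracle in the test-suite):

    sigma'_dev,m = (C/J) e^Qw ( S_m lm~^2 - (1/3) sum_n S_n ln~^2 ),
    sigma'_vol,m = dW_vol/dJ            (equal in r and theta),

where S_m = dQw/dEm / 2 collects the quadratic-form couplings.

Permeability follows the Kozeny-Carman porosity dependence,

    k = k0 * (1-phi_f0)^2/phi_f0^3 * phi_f^3/(1-phi_f)^2,

normalized so that k(phi_f0) = k0.

All functions are pure, broadcast over numpy arrays, and accept complex
dtypes (required by the solver's complex-step Jacobian).  Exponents are
capped at 700 before exponentiation; an overflowing state yields +inf
energy/stress, which the Newton line search treats as a rejected step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PorosityBoundError
from .units import kpa_to_mpa

__all__ = [
    "FungParams",
    "VolumetricParams",
    "PermeabilityParams",
    "StressState",
    "deviatoric_strains",
    "strain_energy",
    "effective_stress",
    "w_vol",
    "dw_vol_dJ",
    "permeability",
]

#: cap on exponents fed to exp(); beyond this the energy is flagged +inf
_EXP_CAP = 700.0

#: Exponents of the Fung quadratic form (aortic media, circ/axial/radial).
_DEFAULT_B = (0.9925, 0.4180, 0.0089, 0.0749, 0.0295, 0.0193)


@dataclass(frozen=True)
class FungParams:
    """Fung-type anisotropic parameters. C in MPa; b1..b6 dimensionless.

    b1, b2, b3 weight the squared circumferential, axial and radial
    deviatoric strains; b4, b5, b6 the theta-z, r-z and theta-r couplings.
    """

    C: float
    b1: float = _DEFAULT_B[0]
    b2: float = _DEFAULT_B[1]
    b3: float = _DEFAULT_B[2]
    b4: float = _DEFAULT_B[3]
    b5: float = _DEFAULT_B[4]
    b6: float = _DEFAULT_B[5]

    def __post_init__(self):
        if not self.C > 0.0:
            raise ValueError(f"C must be positive, got {self.C}")
        for name in ("b1", "b2", "b3", "b4", "b5", "b6"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_kpa(cls, C_kpa: float, **b) -> "FungParams":
        return cls(C=kpa_to_mpa(C_kpa), **b)


@dataclass(frozen=True)
class VolumetricParams:
    """Volumetric penalty parameters. Kv in MPa; beta, gamma dimensionless."""

    Kv: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not self.Kv > 0.0:
            raise ValueError(f"Kv must be positive, got {self.Kv}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 2.0:
            raise ValueError(f"gamma must be >= 2, got {self.gamma}")

    @classmethod
    def from_kpa(cls, Kv_kpa: float, beta: float, gamma: float) -> "VolumetricParams":
        return cls(Kv=kpa_to_mpa(Kv_kpa), beta=beta, gamma=gamma)


@dataclass(frozen=True)
class PermeabilityParams:
    """Kozeny-Carman permeability: k0 in mm^4/(N s), phi_f0 dimensionless."""

    k0: float = 2.8e-3
    phi_f0: float = 0.40

    def __post_init__(self):
        if not self.k0 > 0.0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if not (0.0 < self.phi_f0 < 1.0):
            raise ValueError(f"phi_f0 must lie in (0, 1), got {self.phi_f0}")


@dataclass(frozen=True)
class StressState:
    """Effective and total Cauchy stress components with pore pressure.

    All entries in kPa.  Total stress = effective - p (Terzaghi split)
    componentwise.
    """

    sigma_r_eff: np.ndarray
    sigma_theta_eff: np.ndarray
    p: np.ndarray

    @property
    def sigma_r_total(self):
        return self.sigma_r_eff - self.p

    @property
    def sigma_theta_total(self):
        return self.sigma_theta_eff - self.p


def _capped_exp(x):
    x = np.asarray(x)
    big = np.real(x) > _EXP_CAP
    if np.any(big):
        x = np.where(big, np.inf, x)
    with np.errstate(over="ignore", invalid="ignore"):
        return np.exp(x)


def deviatoric_strains(lam_r, lam_t, lam_z=1.0):
    """Deviatoric Green-Lagrange strains (Er~, Et~, Ez~).

    lm~ = J^(-1/3) lambda_m with J = lam_r * lam_t * lam_z, and
    Em~ = (lm~^2 - 1)/2.
    """
    lam_r = np.asarray(lam_r)
    lam_t = np.asarray(lam_t)
    lam_z = np.asarray(lam_z)
    J = lam_r * lam_t * lam_z
    Jm23 = J ** (-2.0 / 3.0)
    Er = 0.5 * (Jm23 * lam_r**2 - 1.0)
    Et = 0.5 * (Jm23 * lam_t**2 - 1.0)
    Ez = 0.5 * (Jm23 * lam_z**2 - 1.0)
    return Er, Et, Ez


def _fung_core(fung: FungParams, lam_r, lam_t):
    """Shared pieces: (Qw, S_r, S_t, S_z, lr~^2, lt~^2, lz~^2, J)."""
    lam_r = np.asarray(lam_r)
    lam_t = np.asarray(lam_t)
    J = lam_r * lam_t  # lambda_z = 1 (plane strain)
    Jm23 = J ** (-2.0 / 3.0)
    l2r = Jm23 * lam_r**2
    l2t = Jm23 * lam_t**2
    l2z = Jm23
    Er = 0.5 * (l2r - 1.0)
    Et = 0.5 * (l2t - 1.0)
    Ez = 0.5 * (l2z - 1.0)
    Qw = (
        fung.b1 * Et**2
        + fung.b2 * Ez**2
        + fung.b3 * Er**2
        + 2.0 * fung.b4 * Et * Ez
        + 2.0 * fung.b5 * Er * Ez
        + 2.0 * fung.b6 * Et * Er
    )
    # S_m = (1/2) dQw/dEm
    Sr = fung.b3 * Er + fung.b5 * Ez + fung.b6 * Et
    St = fung.b1 * Et + fung.b4 * Ez + fung.b6 * Er
    Sz = fung.b2 * Ez + fung.b4 * Et + fung.b5 * Er
    return Qw, Sr, St, Sz, l2r, l2t, l2z, J


def w_vol(vol: VolumetricParams, J):
    """Volumetric strain energy [MPa], branching on J >= 1."""
    J = np.asarray(J)
    with np.errstate(all="ignore"):
        dJ = J - 1.0
        f = vol.beta * np.where(np.real(dJ) >= 0.0, dJ, 0.0) ** vol.gamma + 0.5 * dJ**2
        f = np.where(np.real(f) > _EXP_CAP, np.inf, f)
        expand = vol.Kv * (np.exp(np.where(np.real(f) > _EXP_CAP, _EXP_CAP, f)) - 1.0)
        expand = np.where(np.isinf(np.real(f)), np.inf, expand)
        Jsafe = np.where(np.real(J) > 0.0, J, 1.0)
        compress = 0.5 * vol.Kv * (0.5 * (Jsafe**2 - 1.0) - np.log(Jsafe))
        out = np.where(np.real(J) >= 1.0, expand, compress)
        out = np.where(np.real(J) > 0.0, out, np.inf)
    return out


def dw_vol_dJ(vol: VolumetricParams, J):
    """dW_vol/dJ [MPa]; continuous (zero) at J = 1."""
    J = np.asarray(J)
    with np.errstate(all="ignore"):
        dJ = J - 1.0
        dJpos = np.where(np.real(dJ) >= 0.0, dJ, 0.0)
        f = vol.beta * dJpos**vol.gamma + 0.5 * dJ**2
        fp = vol.gamma * vol.beta * dJpos ** (vol.gamma - 1.0) + dJ
        ecap = np.exp(np.where(np.real(f) > _EXP_CAP, _EXP_CAP, f))
        expand = vol.Kv * np.where(np.real(f) > _EXP_CAP, np.inf, ecap) * fp
        Jsafe = np.where(np.real(J) > 0.0, J, 1.0)
        compress = 0.5 * vol.Kv * (Jsafe - 1.0 / Jsafe)
        out = np.where(np.real(J) >= 1.0, expand, compress)
        out = np.where(np.real(J) > 0.0, out, np.inf)
    return out


def strain_energy(fung: FungParams, vol: VolumetricParams, lam_r, lam_t):
    """Total strain energy density W = W_dev + W_vol [MPa]."""
    Qw, *_ , J = _fung_core(fung, lam_r, lam_t)
    Wdev = 0.5 * fung.C * (_capped_exp(Qw) - 1.0)
    return Wdev + w_vol(vol, J)


def effective_stress(fung: FungParams, vol: VolumetricParams, lam_r, lam_t):
    """Effective Cauchy stresses (sigma'_r, sigma'_theta) [MPa].

    Closed-form sigma'_m = (lambda_m / J) dW/dlambda_m, with lambda_z = 1
    fixed and the J-dependence (isochoric split and W_vol) differentiated
    through.
    """
    Qw, Sr, St, Sz, l2r, l2t, l2z, J = _fung_core(fung, lam_r, lam_t)
    eQ = _capped_exp(Qw)
    trace = Sr * l2r + St * l2t + Sz * l2z
    pref = fung.C * eQ / J
    sig_r = pref * (Sr * l2r - trace / 3.0)
    sig_t = pref * (St * l2t - trace / 3.0)
    dvol = dw_vol_dJ(vol, J)
    return sig_r + dvol, sig_t + dvol


def permeability(perm: PermeabilityParams, phi_f, check: bool = True):
    """Kozeny-Carman permeability k(phi_f) [mm^4/(N s)]; k(phi_f0) = k0."""
    phi_f = np.asarray(phi_f)
    if check and (np.any(np.real(phi_f) <= 0.0) or np.any(np.real(phi_f) >= 1.0)):
        raise PorosityBoundError(
            f"phi_f out of (0, 1): range "
            f"[{np.min(np.real(phi_f)):.4g}, {np.max(np.real(phi_f)):.4g}]"
        )
    f0 = perm.phi_f0
    with np.errstate(all="ignore"):
        return perm.k0 * ((1.0 - f0) ** 2 / f0**3) * phi_f**3 / (1.0 - phi_f) ** 2
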