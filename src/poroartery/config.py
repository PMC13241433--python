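"""Run configuration: YAML parsing, validation, defaults, hashing.

Configs are flat key groups (geometry, fung, volumetric, permeability,
prestretch, schedule, solver, output).  Pressures are given in mmHg and
moduli in kPa — the units the source experiments and parameter tables use —
and converted centrally to the internal mm-N-s (MPa) system.  The defaults
reproduce the baseline computation: rat-scale arterial geometry a0 = 0.31,
b0 = 0.42 mm, porosity 0.40, k0 = 2.8e-3 mm^4/(N s), the aortic-media Fung
exponents, the best-fit moduli C = 210 kPa, Kv = 9.0 kPa, beta = 1.5,
gamma = 4.8, and N = 100 elements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

from . import constitutive as cst
from . import kinematics as kin
from . import solver as slv
from .errors import ConfigError

__all__ = ["RunConfig", "default_config", "load_config", "dump_config", "config_hash"]

DEFAULT_SCHEDULE = (0.0, 15.0, 40.0, 80.0, 100.0, 120.0, 160.0)


@dataclass
class RunConfig:
    """Aggregated, unit-carrying run configuration (see module docstring)."""

    a0_mm: float = 0.31
    b0_mm: float = 0.42
    phi_f0: float = 0.40
    N: int = 100

    C_kPa: float = 210.0
    b1: float = 0.9925
    b2: float = 0.4180
    b3: float = 0.0089
    b4: float = 0.0749
    b5: float = 0.0295
    b6: float = 0.0193

    Kv_kPa: float = 9.0
    beta: float = 1.5
    gamma: float = 4.8

    k0_mm4_Ns: float = 2.8e-3

    prestretch_case: int = 1
    prestretch_g: float = 0.0

    pressures_mmHg: tuple = DEFAULT_SCHEDULE

    newton_rtol: float = 1.0e-10
    newton_atol: float = 1.0e-12
    max_iter: int = 50
    dp_step_mmHg: float = 5.0
    min_dp_step_mmHg: float = 0.15625

    output_dir: str = "out"

    # ---- structured views -------------------------------------------------

    def reference(self) -> kin.ReferenceConfig:
        return kin.ReferenceConfig(a0=self.a0_mm, b0=self.b0_mm, phi_f0=self.phi_f0, N=self.N)

    def fung(self) -> cst.FungParams:
        return cst.FungParams.from_kpa(
            self.C_kPa, b1=self.b1, b2=self.b2, b3=self.b3,
            b4=self.b4, b5=self.b5, b6=self.b6,
        )

    def volumetric(self) -> cst.VolumetricParams:
        return cst.VolumetricParams.from_kpa(self.Kv_kPa, self.beta, self.gamma)

    def permeability(self) -> cst.PermeabilityParams:
        return cst.PermeabilityParams(k0=self.k0_mm4_Ns, phi_f0=self.phi_f0)

    def prestretch(self) -> kin.PreStretchField | None:
        if self.prestretch_g == 0.0:
            return None
        return kin.PreStretchField(
            ref=self.reference(), g=self.prestretch_g, case=self.prestretch_case
        )

    def model(self) -> slv.Model:
        return slv.Model(
            ref=self.reference(),
            fung=self.fung(),
            vol=self.volumetric(),
            perm=self.permeability(),
            prestretch=self.prestretch(),
        )

    def solver_options(self) -> slv.SolverOptions:
        return slv.SolverOptions(
            newton_rtol=self.newton_rtol,
            newton_atol=self.newton_atol,
            max_iter=self.max_iter,
            dp_step_mmhg=self.dp_step_mmHg,
            min_dp_step_mmhg=self.min_dp_step_mmHg,
        )

    # ---- grouped (file) representation ------------------------------------

    def to_groups(self) -> dict:
        return {
            "geometry": {
                "a0_mm": self.a0_mm, "b0_mm": self.b0_mm,
                "phi_f0": self.phi_f0, "N": self.N,
            },
            "fung": {
                "C_kPa": self.C_kPa,
                **{f"b{i}": getattr(self, f"b{i}") for i in range(1, 7)},
            },
            "volumetric": {"Kv_kPa": self.Kv_kPa, "beta": self.beta, "gamma": self.gamma},
            "permeability": {"k0_mm4_Ns": self.k0_mm4_Ns},
            "prestretch": {"case": self.prestretch_case, "g": self.prestretch_g},
            "schedule": {"pressures_mmHg": list(self.pressures_mmHg)},
            "solver": {
                "newton_rtol": self.newton_rtol,
                "newton_atol": self.newton_atol,
                "max_iter": self.max_iter,
                "dp_step_mmHg": self.dp_step_mmHg,
                "min_dp_step_mmHg": self.min_dp_step_mmHg,
            },
            "output": {"directory": self.output_dir},
        }


_GROUP_FIELDS = {
    "geometry": {"a0_mm", "b0_mm", "phi_f0", "N"},
    "fung": {"C_kPa", "b1", "b2", "b3", "b4", "b5", "b6"},
    "volumetric": {"Kv_kPa", "beta", "gamma"},
    "permeability": {"k0_mm4_Ns"},
    "prestretch": {"case", "g"},
    "schedule": {"pressures_mmHg"},
    "solver": {"newton_rtol", "newton_atol", "max_iter", "dp_step_mmHg", "min_dp_step_mmHg"},
    "output": {"directory"},
}
_RENAME = {
    ("prestretch", "case"): "prestretch_case",
    ("prestretch", "g"): "prestretch_g",
    ("output", "directory"): "output_dir",
}


def from_groups(groups: dict) -> RunConfig:
    kwargs = {}
    for gname, body in groups.items():
        if gname not in _GROUP_FIELDS:
            raise ConfigError(f"unknown config group: {gname!r}")
        if body is None:
            continue
        for key, value in body.items():
            if key not in _GROUP_FIELDS[gname]:
                raise ConfigError(f"unknown config key: {gname}.{key}")
            name = _RENAME.get((gname, key), key)
            if name == "pressures_mmHg":
                value = tuple(float(v) for v in value)
            kwargs[name] = value
    try:
        cfg = RunConfig(**kwargs)
        cfg.model()  # triggers dataclass validation of all parameter groups
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        groups = yaml.safe_load(fh) or {}
    return from_groups(groups)


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_groups(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    """Short deterministic hash of the full configuration."""
    canon = json.dumps(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
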