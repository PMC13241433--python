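"""Apparent deformation measures, error metrics, parameter sweep, and the
pre-stretch homogenization scan.

Apparent (global) deformation measures are built from the current inner and
outer radii relative to their values at a 15 mmHg reference pressure (the
lowest pressure at which inflation rigs hold the vessel reliably open):

    Lambda_r = (b - a) / (b_bar - a_bar)          apparent radial stretch
    Lambda_theta = (b + a) / (b_bar + a_bar)      apparent circumferential
    J_app = (b^2 - a^2) / (b_bar^2 - a_bar^2)     apparent volume ratio

Note J_app = Lambda_r * Lambda_theta identically (difference of squares).

Model-vs-experiment discrepancy is an L1 relative error averaged over the
evaluation pressures (40, 80, 120, 160 mmHg by default) for each measure,
reported in percent; the total error is the sum of the three.  The material
parameters (C, Kv, beta, gamma) are identified by exhaustive Cartesian grid
search ranked by total error.

The residual-stress surrogate is a linear circumferential pre-stretch
gradient g; the homogenizing g minimizes the transmural spread of the
circumferential effective stress, E_var = |max sigma'_theta - min
sigma'_theta|, evaluated at a fixed physiological pressure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import kinematics as kin
from . import solver as slv
from .errors import ConfigError, ConvergenceError

__all__ = [
    "ApparentMeasures",
    "ErrorReport",
    "SweepResult",
    "PreStretchScan",
    "apparent_measures",
    "error_measure",
    "grid_axes",
    "grid_size",
    "parameter_sweep",
    "prestretch_scan",
    "select_minimum",
    "refine_minimum",
    "evar_kpa",
    "read_experiment_csv",
    "write_experiment_csv",
    "EXPERIMENT_COLUMNS",
]

#: CSV schema for (pseudo-)experimental apparent-deformation records
EXPERIMENT_COLUMNS = ("dp_mmHg", "lambda_r_apparent", "lambda_theta_apparent", "j_apparent")

#: default reference and error-evaluation pressures [mmHg]
REFERENCE_DP = 15.0
ERROR_PRESSURES = (40.0, 80.0, 120.0, 160.0)


@dataclass(frozen=True)
class ApparentMeasures:
    """Apparent deformation measures per pressure, referenced to 15 mmHg."""

    pressures: np.ndarray
    Lambda_r: np.ndarray
    Lambda_theta: np.ndarray
    J_app: np.ndarray
    a_bar: float
    b_bar: float

    def at(self, dp: float) -> tuple[float, float, float]:
        idx = np.flatnonzero(np.isclose(self.pressures, dp, atol=1.0e-9))
        if idx.size == 0:
            raise ConfigError(f"no apparent measures at dp = {dp} mmHg")
        i = int(idx[0])
        return (
            float(self.Lambda_r[i]),
            float(self.Lambda_theta[i]),
            float(self.J_app[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dp_mmHg": self.pressures,
                "lambda_r_apparent": self.Lambda_r,
                "lambda_theta_apparent": self.Lambda_theta,
                "j_apparent": self.J_app,
            }
        )


def apparent_measures(sols: list[slv.Solution], ref_dp: float = REFERENCE_DP) -> ApparentMeasures:
    """Apparent measures from a pressure sweep containing the reference level."""
    dps = np.array([s.dp_mmhg for s in sols])
    ref = [s for s in sols if math.isclose(s.dp_mmhg, ref_dp, abs_tol=1.0e-9)]
    if not ref:
        raise ConfigError(f"sweep does not contain the reference pressure {ref_dp} mmHg")
    a_bar, b_bar = ref[0].a, ref[0].b
    a = np.array([s.a for s in sols])
    b = np.array([s.b for s in sols])
    return ApparentMeasures(
        pressures=dps,
        Lambda_r=(b - a) / (b_bar - a_bar),
        Lambda_theta=(b + a) / (b_bar + a_bar),
        J_app=(b**2 - a**2) / (b_bar**2 - a_bar**2),
        a_bar=a_bar,
        b_bar=b_bar,
    )


@dataclass(frozen=True)
class ErrorReport:
    """L1 relative errors [%] of the three apparent measures; total is the sum."""

    E_Lambda_r: float
    E_Lambda_theta: float
    E_J: float
    pressures: tuple
    per_pressure: pd.DataFrame = field(repr=False)

    @property
    def E_tot(self) -> float:
        return self.E_Lambda_r + self.E_Lambda_theta + self.E_J


def _exp_lookup(exp: pd.DataFrame, dp: float) -> pd.Series:
    rows = exp[np.isclose(exp["dp_mmHg"].to_numpy(dtype=float), dp, atol=1.0e-9)]
    if rows.empty:
        raise ConfigError(f"experimental data missing dp = {dp} mmHg")
    return rows.iloc[0]


def error_measure(
    sim: ApparentMeasures,
    exp: pd.DataFrame,
    pressures=ERROR_PRESSURES,
) -> ErrorReport:
    """Mean L1 relative error of each apparent measure over ``pressures``.

    ``exp`` follows the experiment CSV schema.  A zero experimental value
    would divide by zero and raises :class:`ConfigError`.
    """
    cols = ("lambda_r_apparent", "lambda_theta_apparent", "j_apparent")
    contrib = {c: [] for c in cols}
    for dp in pressures:
        row = _exp_lookup(exp, dp)
        sim_vals = sim.at(dp)
        for c, sv in zip(cols, sim_vals):
            xe = float(row[c])
            if xe == 0.0:
                raise ConfigError(f"zero experimental value for {c} at {dp} mmHg")
            contrib[c].append(abs((sv - xe) / xe))
    per = pd.DataFrame(contrib, index=list(pressures)) * 100.0
    return ErrorReport(
        E_Lambda_r=float(per["lambda_r_apparent"].mean()),
        E_Lambda_theta=float(per["lambda_theta_apparent"].mean()),
        E_J=float(per["j_apparent"].mean()),
        pressures=tuple(pressures),
        per_pressure=per,
    )


# ---------------------------------------------------------------------------
# parameter sweep


def grid_axes(stride: int | tuple[int, int, int, int] = 1) -> dict[str, np.ndarray]:
    """Cartesian sweep axes (C, Kv in kPa; beta, gamma dimensionless).

    Full resolution: C in [20, 300] step 10 (29 values), Kv in [5, 50]
    step 1 (46), beta in [0.1, 3.0] step 0.1 (30), gamma in [2, 10] step 0.2
    (41) — 1,640,820 combinations.  ``stride`` thins each axis for
    desk-scale runs (a common int or one per axis).
    """
    if isinstance(stride, int):
        stride = (stride,) * 4
    axes = {
        "C_kPa": 20.0 + 10.0 * np.arange(29),
        "Kv_kPa": 5.0 + 1.0 * np.arange(46),
        "beta": np.round(0.1 + 0.1 * np.arange(30), 10),
        "gamma": np.round(2.0 + 0.2 * np.arange(41), 10),
    }
    return {k: v[::s] for (k, v), s in zip(axes.items(), stride)}


def grid_size(axes: dict[str, np.ndarray] | None = None) -> int:
    axes = grid_axes() if axes is None else axes
    return int(np.prod([len(v) for v in axes.values()]))


@dataclass
class SweepResult:
    """Ranked grid-search result.

    ``table`` holds one row per combination in deterministic grid order;
    ``ranked`` sorts converged rows by (E_tot, C, Kv, beta, gamma)
    ascending; ``best_fit`` is the first ranked row and ``top_subset`` the
    lowest-error fraction (floor, minimum 1 row).
    """

    table: pd.DataFrame
    top_fraction: float = 0.01

    @property
    def converged_table(self) -> pd.DataFrame:
        return self.table[self.table["converged"]]

    @property
    def ranked(self) -> pd.DataFrame:
        return self.converged_table.sort_values(
            ["E_tot", "C_kPa", "Kv_kPa", "beta", "gamma"], kind="mergesort"
        )

    @property
    def best_fit(self) -> pd.Series:
        ranked = self.ranked
        if ranked.empty:
            raise ConvergenceError("no converged sweep case")
        return ranked.iloc[0]

    @property
    def top_subset(self) -> pd.DataFrame:
        ranked = self.ranked
        n = max(1, math.floor(self.top_fraction * len(ranked)))
        return ranked.iloc[:n]


def parameter_sweep(
    exp: pd.DataFrame,
    ref: kin.ReferenceConfig,
    perm,
    axes: dict[str, np.ndarray] | None = None,
    prestretch: kin.PreStretchField | None = None,
    options: slv.SolverOptions | None = None,
    pressures=(REFERENCE_DP,) + ERROR_PRESSURES,
    err_pressures=ERROR_PRESSURES,
    top_fraction: float = 0.01,
) -> SweepResult:
    """Exhaustive Cartesian grid search of (C, Kv, beta, gamma).

    Runs the forward model per combination (in deterministic grid order;
    the result is independent of execution order), evaluates the apparent
    measures against ``exp`` and ranks by total error.  Non-converged
    combinations are recorded with NaN errors and excluded from ranking.
    """
    from . import constitutive as cst

    axes = grid_axes() if axes is None else axes
    rows = []
    for C, Kv, beta, gamma in itertools.product(*axes.values()):
        model = slv.Model(
            ref=ref,
            fung=cst.FungParams.from_kpa(float(C)),
            vol=cst.VolumetricParams.from_kpa(float(Kv), float(beta), float(gamma)),
            perm=perm,
            prestretch=prestretch,
        )
        row = {"C_kPa": float(C), "Kv_kPa": float(Kv), "beta": float(beta), "gamma": float(gamma)}
        try:
            sols = slv.pressure_sweep(model, pressures, options)
            rep = error_measure(apparent_measures(sols), exp, err_pressures)
        except ConvergenceError:
            row.update(
                E_Lambda_r=np.nan, E_Lambda_theta=np.nan, E_J=np.nan,
                E_tot=np.nan, converged=False,
            )
        else:
            row.update(
                E_Lambda_r=rep.E_Lambda_r,
                E_Lambda_theta=rep.E_Lambda_theta,
                E_J=rep.E_J,
                E_tot=rep.E_tot,
                converged=True,
            )
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), top_fraction=top_fraction)


# ---------------------------------------------------------------------------
# pre-stretch homogenization scan


def evar_kpa(sol: slv.Solution) -> float:
    """Transmural spread of the circumferential effective stress [kPa]."""
    return float(np.max(sol.sigma_t_eff) - np.min(sol.sigma_t_eff))


@dataclass
class PreStretchScan:
    """E_var(g) scan for one radial-coupling case at one evaluation pressure."""

    case: int
    dp_eval_mmhg: float
    table: pd.DataFrame
    states: dict[float, np.ndarray] = field(repr=False, default_factory=dict)

    def nearest_state(self, g: float) -> np.ndarray | None:
        if not self.states:
            return None
        g0 = min(self.states, key=lambda gg: abs(gg - g))
        return self.states[g0]


def _solve_at_g(model_base, case, g, dp_eval, options, x_warm):
    model = model_base.with_prestretch(g=float(g), case=case)
    if x_warm is not None:
        try:
            return model, slv.solve_at_pressure(dp_eval, model, x0=x_warm, options=options)
        except ConvergenceError:
            pass
    sols = slv.pressure_sweep(model, [dp_eval], options)
    return model, sols[-1]


def prestretch_scan(
    model_base: slv.Model,
    case: int,
    g_values,
    dp_eval_mmhg: float = 100.0,
    options: slv.SolverOptions | None = None,
) -> PreStretchScan:
    """Scan the pre-stretch gradient g, recording E_var at ``dp_eval_mmhg``.

    Consecutive gradients warm-start each other (a single Newton solve per
    g); a failed warm start falls back to full pressure continuation, and a
    still-failing g is recorded as non-converged.
    """
    g_values = np.asarray(list(g_values), dtype=float)
    rows, states = [], {}
    x_warm = None
    for g in g_values:
        try:
            _, sol = _solve_at_g(model_base, case, g, dp_eval_mmhg, options, x_warm)
        except ConvergenceError:
            rows.append({"g": g, "E_var_kPa": np.nan, "converged": False})
            continue
        x_warm = sol.x
        states[float(g)] = sol.x.copy()
        rows.append({"g": float(g), "E_var_kPa": evar_kpa(sol), "converged": True})
    return PreStretchScan(
        case=case, dp_eval_mmhg=dp_eval_mmhg, table=pd.DataFrame(rows), states=states
    )


def select_minimum(scan: PreStretchScan) -> tuple[float, float]:
    """Interior local minimum of E_var(g) with the smallest E_var.

    Raises :class:`ConfigError` if the scan has no interior local minimum
    (E_var monotone over the scanned range).
    """
    tab = scan.table[scan.table["converged"]].reset_index(drop=True)
    g = tab["g"].to_numpy()
    E = tab["E_var_kPa"].to_numpy()
    if len(E) < 3:
        raise ConfigError("scan too short to locate a local minimum")
    interior = [
        i for i in range(1, len(E) - 1) if E[i] <= E[i - 1] and E[i] <= E[i + 1]
    ]
    if not interior:
        raise ConfigError("no interior local minimum of E_var on the scanned range")
    i = min(interior, key=lambda j: E[j])
    return float(g[i]), float(E[i])


def refine_minimum(
    model_base: slv.Model,
    scan: PreStretchScan,
    options: slv.SolverOptions | None = None,
    xatol: float = 1.0e-5,
) -> tuple[float, float]:
    """Refine the selected scan minimum by bounded scalar minimization.

    Returns (g_min, E_var_min[kPa]).  Solves warm-start from the nearest
    scanned state.
    """
    g0, _ = select_minimum(scan)
    tab = scan.table[scan.table["converged"]]
    g = tab["g"].to_numpy()
    i = int(np.argmin(np.abs(g - g0)))
    lo = g[max(0, i - 1)]
    hi = g[min(len(g) - 1, i + 1)]

    def objective(gg: float) -> float:
        _, sol = _solve_at_g(
            model_base, scan.case, gg, scan.dp_eval_mmhg, options, scan.nearest_state(gg)
        )
        return evar_kpa(sol)

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    return float(res.x), float(res.fun)


# ---------------------------------------------------------------------------
# experiment CSV I/O


def read_experiment_csv(path) -> pd.DataFrame:
    """Read an apparent-deformation CSV (lines starting with # are metadata)."""
    df = pd.read_csv(path, comment="#")
    missing = set(EXPERIMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"experiment CSV missing columns: {sorted(missing)}")
    return df


def write_experiment_csv(df: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
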