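"""Parameter sweeps, power-law scaling fits and the hydraulic-diameter
collapse analysis.

Transit time versus constriction curvature radius follows a power law
T = c * R^p in both channel families; ``fit_power_law`` recovers (c, p) by
ordinary least squares in log-log space and ``crossing_radius`` locates
the radius at which two such laws intersect.  ``dh_collapse`` groups sweep
rows by throat hydraulic diameter and reports the spread of T within each
group — the collapse diagnostic showing that transit time is dominated by
the throat hydraulic diameter rather than the aspect ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AxisymChannel, hydraulic_diameter, squeeze_length
from .scenarios import RunConfig, ScenarioGrid
from .simulator import ModelParams, TransitSimulator

__all__ = [
    "PowerLawFit",
    "run_sweep",
    "fit_power_law",
    "eval_power_law",
    "crossing_radius",
    "dh_collapse",
]


@dataclass(frozen=True)
class PowerLawFit:
    """y = coeff * x^exponent with OLS diagnostics in log space."""

    coeff: float
    exponent: float
    r_squared: float = 1.0
    n: int = 0


def _throat_metrics(cfg: RunConfig):
    ch = cfg.channel
    if isinstance(ch, AxisymChannel):
        d_h = 2.0 * ch.r_min
        aspect = 1.0
    else:
        d_h = hydraulic_diameter(ch.H, ch.W_con)
        aspect = ch.H / ch.W_con
    fc = squeeze_length(ch, cfg.cell.R_cell)
    return d_h, aspect, fc


def run_sweep(
    grid: ScenarioGrid | list[RunConfig],
    params: ModelParams | None = None,
    dt: float | None = None,
) -> pd.DataFrame:
    """Simulate every config of a grid; one row per config.

    Failures of individual runs are recorded (completed = False, T = NaN)
    rather than raised.  Deterministic given the configs.
    """
    configs = list(grid)
    rows = []
    for cfg in configs:
        d_h, aspect, fc = _throat_metrics(cfg)
        row = {
            "config_id": cfg.config_id,
            "varied_name": cfg.varied_name,
            "varied_value": cfg.varied_value,
            "throat_D_h": d_h,
            "aspect_ratio": aspect,
            "squeeze_length": fc.s if fc.contact_exists else math.nan,
            "theta_first_contact": fc.theta if fc.contact_exists else math.nan,
            "T": math.nan,
            "completed": False,
        }
        try:
            sim = TransitSimulator(
                cfg.channel, cfg.cell, cfg.plasma, cfg.dP_total,
                dt or cfg.dt, params,
            )
            rec = sim.run()
            row["completed"] = bool(rec.completed)
            if rec.T is not None:
                row["T"] = rec.T
        except Exception as exc:  # per-row status, not fatal
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_power_law(x, y) -> PowerLawFit:
    """OLS fit of log y on log x; exact on noiseless power-law data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs positive data")
    lx, ly = np.log(x), np.log(y)
    exponent, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + exponent * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        coeff=float(np.exp(intercept)), exponent=float(exponent),
        r_squared=r2, n=int(x.size),
    )


def eval_power_law(fit: PowerLawFit, x):
    """coeff * x^exponent."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    out = fit.coeff * x ** fit.exponent
    return float(out) if out.ndim == 0 else out


def crossing_radius(fit1: PowerLawFit, fit2: PowerLawFit) -> float:
    """Abscissa where two power laws intersect:
    (c2/c1)^(1/(p1 - p2))."""
    dp = fit1.exponent - fit2.exponent
    if abs(dp) < 1e-14:
        raise ValueError("equal exponents: no crossing")
    return float((fit2.coeff / fit1.coeff) ** (1.0 / dp))


def dh_collapse(sweep: pd.DataFrame, tol: float = 0.10,
                decimals: int = 2) -> pd.DataFrame:
    """Group completed sweep rows by (rounded) throat hydraulic diameter
    and report mean T and the maximum relative deviation within each
    group; ``violates`` flags groups spreading beyond ``tol``."""
    if len(sweep) < 1:
        raise ValueError("need at least one sweep row")
    df = sweep[np.isfinite(sweep["T"])].copy()
    df["D_h_group"] = df["throat_D_h"].round(decimals)
    out = []
    for dh, grp in df.groupby("D_h_group"):
        mean_t = grp["T"].mean()
        dev = float(np.max(np.abs(grp["T"] - mean_t) / mean_t)) if len(grp) > 1 else 0.0
        out.append(
            {"throat_D_h": dh, "n": len(grp), "mean_T": mean_t,
             "max_rel_dev": dev, "violates": dev > tol}
        )
    return pd.DataFrame(out)
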