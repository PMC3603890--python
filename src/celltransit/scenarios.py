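"""Study scenario grids and synthetic fixtures.

``paper_grid`` returns the exact parameter grids of the study design:
the control rectangular channel (H = 8.2 um, R_con = 27.525 um,
W_con = 4.368 um at dP = 40 Pa), the channel-height sweep over
[7.2, 16.2] um, the throat-width set {3.112, 4.368, 5.7} um (equal area /
equal hydraulic diameter / equal width relative to the 5.7 um axisymmetric
throat), the curvature-radius set {16.15, 27.525, 42.15} um, the
equal-hydraulic-diameter aspect-ratio set, and the reference axisymmetric
capillary.

``random_grid`` draws reproducible valid geometries for property tests;
``synthetic_velocity_trace`` and ``synthetic_powerlaw_samples`` build
fixtures with known structure for the peak-detection and fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AxisymChannel, RectChannel, hydraulic_diameter
from .leakage import Plasma
from .rheology import CellModel
from .simulator import TransitRecord

__all__ = [
    "RunConfig",
    "ScenarioGrid",
    "paper_grid",
    "random_grid",
    "synthetic_velocity_trace",
    "synthetic_powerlaw_samples",
    "HEIGHT_SWEEP_H",
    "WIDTH_SWEEP_WCON",
    "RADIUS_SWEEP_RCON",
    "ASPECT_TABLE",
]

#: channel-height sweep: printed endpoints 7.2 and 16.2 um plus the printed
#: minimum location 10.86 um, filled at ~1 um spacing
HEIGHT_SWEEP_H = (7.2, 8.2, 9.2, 10.2, 10.86, 11.2, 12.2, 14.2, 16.2)
WIDTH_SWEEP_WCON = (3.112, 4.368, 5.7)
RADIUS_SWEEP_RCON = (16.15, 27.525, 42.15)
#: (H, W_con) pairs sharing the 5.70 um throat hydraulic diameter
ASPECT_TABLE = ((7.2, 4.717), (8.2, 4.368), (10.2, 3.955))

CONTROL_H = 8.2
CONTROL_RCON = 27.525
CONTROL_WCON = 4.368
DEFAULT_DP = 40.0
DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class RunConfig:
    """One complete simulation configuration."""

    config_id: str
    channel: RectChannel | AxisymChannel
    cell: CellModel = field(default_factory=CellModel)
    plasma: Plasma = field(default_factory=Plasma)
    dP_total: float = DEFAULT_DP
    dt: float = DEFAULT_DT
    provenance: str = "paper-control"
    varied_name: str = ""
    varied_value: float = math.nan


@dataclass(frozen=True)
class ScenarioGrid:
    name: str
    configs: tuple[RunConfig, ...]

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)


def _rect(H, R_con=CONTROL_RCON, W_con=CONTROL_WCON) -> RectChannel:
    return RectChannel(H=H, R_con=R_con, W_con=W_con)


def paper_grid(experiment: str) -> ScenarioGrid:
    """Exact scenario grid of one of the study's experiments.

    ``experiment`` is one of control, height, width, radius, aspect, axisym.
    """
    if experiment == "control":
        cfgs = [
            RunConfig("control", _rect(CONTROL_H), provenance="paper-control",
                      varied_name="W_con", varied_value=CONTROL_WCON)
        ]
    elif experiment == "height":
        cfgs = [
            RunConfig(f"H={h}", _rect(h), provenance="paper-sweep",
                      varied_name="H", varied_value=h)
            for h in HEIGHT_SWEEP_H
        ]
    elif experiment == "width":
        cfgs = [
            RunConfig(f"Wcon={w}", _rect(CONTROL_H, W_con=w),
                      provenance="paper-sweep", varied_name="W_con",
                      varied_value=w)
            for w in WIDTH_SWEEP_WCON
        ]
    elif experiment == "radius":
        cfgs = [
            RunConfig(f"Rcon={r}", _rect(CONTROL_H, R_con=r),
                      provenance="paper-sweep", varied_name="R_con",
                      varied_value=r)
            for r in RADIUS_SWEEP_RCON
        ]
    elif experiment == "aspect":
        cfgs = [
            RunConfig(f"aspect H={h}", _rect(h, W_con=w),
                      provenance="paper-sweep", varied_name="H/W_con",
                      varied_value=h / w)
            for h, w in ASPECT_TABLE
        ]
    elif experiment == "axisym":
        cfgs = [
            RunConfig("axisym", AxisymChannel(), provenance="paper-control",
                      varied_name="r_con", varied_value=CONTROL_RCON)
        ]
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return ScenarioGrid(name=experiment, configs=tuple(cfgs))


def random_grid(
    seed: int,
    n: int,
    H_range=(7.2, 16.2),
    R_con_range=(15.0, 45.0),
    W_con_range=(2.6, 7.6),
) -> ScenarioGrid:
    """Reproducible random grid of valid squeezing geometries.

    Every config has W_con/2 - delta < R_cell (the cell must contact the
    constriction) and W_con < W; same seed, same grid.
    """
    rng = np.random.default_rng(seed)
    cell = CellModel()
    if W_con_range[0] / 2.0 - 0.1 >= cell.R_cell or W_con_range[1] >= 22.36:
        raise ValueError("infeasible parameter ranges")
    cfgs = []
    for i in range(n):
        H = rng.uniform(*H_range)
        R = rng.uniform(*R_con_range)
        W = rng.uniform(*W_con_range)
        ch = RectChannel(H=round(H, 4), R_con=round(R, 4), W_con=round(W, 4))
        cfgs.append(
            RunConfig(f"rand-{i}", ch, provenance="random",
                      varied_name="random", varied_value=float(i))
        )
    return ScenarioGrid(name=f"random-{seed}", configs=tuple(cfgs))


def synthetic_velocity_trace(
    seed: int,
    peak_times=(0.05, 0.90),
    peak_widths=(0.01, 0.01),
    baseline: float = 20.0,
    peak_height: float = 500.0,
    noise: float = 0.0,
    t_end: float = 1.0,
    dt: float = 1e-3,
) -> TransitRecord:
    """Smooth velocity trace with Gaussian peaks at known times (fixture
    for the transit-time definition)."""
    t = np.arange(dt, t_end + dt / 2, dt)
    if np.any(np.asarray(peak_times) > t_end):
        raise ValueError("peak times outside trace span")
    v = np.full_like(t, baseline)
    for tp, wp in zip(peak_times, peak_widths):
        v += peak_height * np.exp(-0.5 * ((t - tp) / wp) ** 2)
    if noise > 0:
        rng = np.random.default_rng(seed)
        v += rng.normal(0.0, noise * peak_height, size=t.size)
    x = np.cumsum(v) * dt
    n = t.size
    z = np.zeros(n)
    return TransitRecord(
        t=t, x=x, v=v, dP_cell=np.full(n, np.nan), w=z, h=z, c=z,
        r_fillet=z, contact_side=z.astype(bool), contact_cf=z.astype(bool),
        gutter_conductance=z, gutters_united=z.astype(bool),
        completed=True,
    )


def synthetic_powerlaw_samples(
    seed: int, coeff: float, exponent: float, x, noise_sigma: float = 0.0
):
    """(x, y) samples of y = coeff * x^exponent * exp(N(0, sigma))."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    y = coeff * x ** exponent
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y * np.exp(rng.normal(0.0, noise_sigma, size=x.shape))
    return x, y
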