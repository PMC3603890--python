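"""Plasma bypass hydraulics: gutter flow and pressure partitioning.

At the micrometre scale of these channels the Reynolds number is far below
one, so every conduit is a Poiseuille resistor.  The channel with a plugged
cell is a series-parallel network: open duct upstream, the cell-occluded
span (bypassed by the corner gutters and, for tall channels, by united
ceiling/floor clearances), and open duct downstream.  The pressure drop
across the occluded span is what drives the cell.

Gutter conductance uses the duct shape-factor form

    G = k * A^3 / (mu * P^2 * L),

with ``A`` the gutter cross-section area, ``P`` its wetted perimeter and
``k = 0.5``, which reproduces Hagen-Poiseuille exactly for a circular
section and sits between the slot and circular limits for intermediate
shapes.  Open rectangular ducts use the Shah-London friction-factor
polynomial, accurate to ~0.1% against the exact double-series solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AxisymChannel, RectChannel, X_INLET

__all__ = [
    "Plasma",
    "Gutter",
    "GutterNetwork",
    "gutter_conductance",
    "pressure_partition",
    "rect_duct_conductance",
    "circular_duct_conductance",
    "open_channel_resistance",
    "open_channel_conductance",
]

GUTTER_SHAPE_FACTOR = 0.5


@dataclass(frozen=True)
class Plasma:
    """Newtonian suspending plasma; flow is inertia-free so only the
    viscosity enters the hydraulics (density recorded)."""

    mu_p: float = 1.2e-3   # Pa*s
    rho_p: float = 1.03e3  # kg/m^3, recorded

    def __post_init__(self):
        if self.mu_p <= 0 or self.rho_p <= 0:
            raise ValueError("plasma properties must be positive")


@dataclass(frozen=True)
class Gutter:
    """One bypass conduit alongside the cell: cross-section area (um^2)
    and wetted perimeter (um)."""

    area: float
    perimeter: float


@dataclass(frozen=True)
class GutterNetwork:
    """Bypass conduits along the occluded span.

    ``united`` flags the tall-channel regime in which each pair of
    ceiling-side and floor-side corner gutters has merged into a single
    clearance above/below the cell.  ``plug_conductance`` is the
    conductance of the cell-advection branch (the flux a moving plug
    carries per unit pressure); when ``None`` the open-duct conductance of
    the occluded span is used, i.e. the span behaves like the bare duct.
    """

    gutters: tuple[Gutter, ...] = ()
    united: bool = False
    plug_conductance: float | None = None

    @property
    def n_gutters(self) -> int:
        return len(self.gutters)


def rect_duct_conductance(height: float, width: float, length: float, mu: float) -> float:
    """Poiseuille conductance Q/dP of a rectangular duct (um^3 / (Pa s)).

    Shah-London polynomial for the Darcy friction factor of a rectangular
    section, f*Re = 96*(1 - 1.3553 a + 1.9467 a^2 - 1.7012 a^3 + 0.9564 a^4
    - 0.2537 a^5) with aspect ratio a = short/long side.
    """
    if min(height, width, length) <= 0:
        raise ValueError("duct dimensions must be positive")
    a = min(height, width) / max(height, width)
    c_darcy = 96.0 * (
        1.0 - 1.3553 * a + 1.9467 * a**2 - 1.7012 * a**3 + 0.9564 * a**4 - 0.2537 * a**5
    )
    area = height * width
    dh = 2.0 * height * width / (height + width)
    return 2.0 * area * dh * dh / (c_darcy * mu * length)


def circular_duct_conductance(radius: float, length: float, mu: float) -> float:
    """Hagen-Poiseuille conductance pi r^4 / (8 mu L)."""
    return math.pi * radius**4 / (8.0 * mu * length)


def gutter_conductance(
    network: GutterNetwork,
    occluded_length: float,
    plasma: Plasma,
    k: float = GUTTER_SHAPE_FACTOR,
) -> float:
    """Total bypass conductance of the gutters over the occluded span.

    Zero when every gutter has zero area (the axisymmetric model seals
    perfectly); halves when the occluded length doubles.
    """
    if occluded_length <= 0:
        raise ValueError("occluded_length must be positive")
    total = 0.0
    for g in network.gutters:
        if g.area <= 0.0 or g.perimeter <= 0.0:
            continue
        total += k * g.area**3 / (plasma.mu_p * g.perimeter**2 * occluded_length)
    return total


# ---------------------------------------------------------------------------
# open-channel resistance, cached as a cumulative integral per channel


_res_cache: dict = {}


def _cumulative_resistance(channel, plasma: Plasma, n: int = 3001):
    key = (channel, plasma.mu_p)
    hit = _res_cache.get(key)
    if hit is not None:
        return hit
    xs = np.linspace(X_INLET, channel.x_outlet, n)
    if isinstance(channel, AxisymChannel):
        r = channel.radius_at(xs)
        g_per_len = math.pi * r**4 / (8.0 * plasma.mu_p)
    else:
        hw = channel.half_width_at(xs)
        h = channel.height_at(xs)
        g_per_len = np.array(
            [rect_duct_conductance(hi, 2.0 * wi, 1.0, plasma.mu_p) for hi, wi in zip(h, hw)]
        )
    integrand = 1.0 / g_per_len
    cum = np.concatenate(
        [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) * 0.5 * np.diff(xs))]
    )
    _res_cache[key] = (xs, cum)
    return xs, cum


def open_channel_resistance(channel, x1: float, x2: float, plasma: Plasma) -> float:
    """Poiseuille resistance (Pa s / um^3) of the open lumen between two
    axial stations, integrating the local cross-section."""
    xs, cum = _cumulative_resistance(channel, plasma)
    r1, r2 = np.interp([x1, x2], xs, cum)
    return float(abs(r2 - r1))


def open_channel_conductance(channel, plasma: Plasma) -> float:
    """End-to-end conductance of the empty channel."""
    return 1.0 / open_channel_resistance(channel, X_INLET, channel.x_outlet, plasma)


def pressure_partition(
    dP_total: float,
    cell_span: tuple[float, float],
    channel,
    network: GutterNetwork,
    plasma: Plasma,
    k: float = GUTTER_SHAPE_FACTOR,
) -> float:
    """Pressure drop across the cell-occluded span of the channel.

    Series circuit: R_up (inlet -> occluded span), the occluded span with
    conductance G_gutters + G_plug, and R_down (span -> outlet):

        dP_cell = dP_total * R_occ / (R_up + R_occ + R_down).

    With sealed gutters and no moving plug the occluded span behaves like
    the bare duct (its open-duct resistance); with infinite gutter
    conductance the span is short-circuited and dP_cell -> 0.
    """
    if dP_total < 0:
        raise ValueError("dP_total must be non-negative")
    x_lo, x_hi = cell_span
    if x_hi <= x_lo:
        raise ValueError("empty occluded span")
    length = x_hi - x_lo
    g_gut = gutter_conductance(network, length, plasma, k) if network.gutters else 0.0
    if network.plug_conductance is not None:
        g_plug = network.plug_conductance
    else:
        g_plug = 1.0 / open_channel_resistance(channel, x_lo, x_hi, plasma)
    g_occ = g_gut + g_plug
    r_up = open_channel_resistance(channel, X_INLET, x_lo, plasma)
    r_down = open_channel_resistance(channel, x_hi, channel.x_outlet, plasma)
    if g_occ <= 0.0:
        return dP_total
    r_occ = 1.0 / g_occ
    return dP_total * r_occ / (r_up + r_occ + r_down)
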