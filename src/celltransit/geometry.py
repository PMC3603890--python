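"""Exact geometry of the two constricted-channel models.

Two channel families are represented:

* :class:`AxisymChannel` — a straight cylindrical pipe with an axisymmetric
  arc-shaped constriction, the classical tube-flow idealisation of an
  alveolar capillary segment.
* :class:`RectChannel` — a rectangular channel whose side walls carry
  arc-shaped constrictions, the sheet-flow (photolithography) counterpart.

Both carry an *imaginary wall*: a numerical surface offset ``delta`` into the
lumen on which the cell slides frictionlessly while plasma penetrates it.
The offset is applied as a normal offset of every bounding surface (the
constriction arc radius grows by ``delta`` about an unchanged centre;
flat walls move in by ``delta``).

Coordinates: ``x`` is axial with the throat plane at ``x = 0`` and the inlet
at ``x = -50`` um; ``y`` is lateral, ``z`` vertical; all lengths in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "OutOfDomainError",
    "AxisymChannel",
    "RectChannel",
    "LumenSection",
    "FirstContact",
    "axisym_radius_at",
    "constricted_region_length",
    "rect_half_width_at",
    "rect_height_at",
    "hydraulic_diameter",
    "equal_area_width",
    "equal_dh_width",
    "squeeze_length",
    "contact_angle_first_contact",
]

X_INLET = -50.0


class GeometryError(ValueError):
    """A channel parameterisation is internally inconsistent."""


class OutOfDomainError(GeometryError):
    """An axial station lies outside the channel."""


@dataclass(frozen=True)
class LumenSection:
    """Cross-section of the lumen at one axial station.

    ``half_width`` and ``height`` are the effective (rectangular) lumen
    dimensions; for the axisymmetric pipe both equal the local radius and
    the area/perimeter are those of the circle.
    """

    x: float
    half_width: float
    height: float
    area: float
    perimeter: float

    @property
    def D_h(self) -> float:
        return 4.0 * self.area / self.perimeter


@dataclass(frozen=True)
class FirstContact:
    """First tangency of the (spherical) cell with the constriction side wall.

    ``s`` is the squeeze length: axial distance from the throat plane to the
    sphere centre at first contact.  ``theta`` is the contact angle, the
    elevation from the x-axis (at the cell centre) to the contact point.
    """

    s: float
    theta: float
    contact_exists: bool


def _check_domain(channel, x) -> np.ndarray:
    xa = np.asarray(x, dtype=float)
    if np.any(xa < X_INLET - 1e-12) or np.any(xa > channel.x_outlet + 1e-12):
        raise OutOfDomainError(
            f"axial station outside [{X_INLET}, {channel.x_outlet}] um"
        )
    return xa


@dataclass(frozen=True)
class AxisymChannel:
    """Straight pipe of radius ``r_pipe`` with an arc constriction.

    Defaults are the reference capillary: curvature radius 27.525 um and
    throat radius 2.85 um, giving an imaginary throat radius of 2.75 um and
    a 26 um constricted region.
    """

    L: float = 150.0
    r_pipe: float = 6.0
    r_con: float = 27.525
    r_min: float = 2.85
    delta: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.r_min <= self.r_pipe):
            raise GeometryError("need 0 < r_min <= r_pipe")
        if not (0.0 <= self.delta < self.r_min):
            raise GeometryError("need 0 <= delta < r_min")
        if self.r_con <= 0 or self.L <= 0:
            raise GeometryError("r_con and L must be positive")
        # the offset arc must reach back to the pipe wall
        self.half_span(True)

    @property
    def x_outlet(self) -> float:
        return X_INLET + self.L

    @property
    def arc_center_r(self) -> float:
        """Radial position of the constriction-arc centre."""
        return self.r_min + self.r_con

    def half_span(self, use_imaginary: bool) -> float:
        """Axial half-length of the (possibly offset) constricted region."""
        R = self.r_con + (self.delta if use_imaginary else 0.0)
        gap = self.arc_center_r - self.r_pipe
        val = R * R - gap * gap
        if val < 0:
            raise GeometryError("constriction arc does not reach the pipe wall")
        return math.sqrt(val)

    def radius_at(self, x, use_imaginary: bool = False):
        xa = _check_domain(self, x)
        R = self.r_con + (self.delta if use_imaginary else 0.0)
        span = self.half_span(use_imaginary)
        inside = np.abs(xa) < span
        r = np.where(
            inside,
            self.arc_center_r - np.sqrt(np.maximum(R * R - xa * xa, 0.0)),
            self.r_pipe,
        )
        return float(r) if np.isscalar(x) or np.ndim(x) == 0 else r

    def section(self, x, use_imaginary: bool = False) -> LumenSection:
        r = self.radius_at(x, use_imaginary)
        return LumenSection(
            x=float(x),
            half_width=r,
            height=2.0 * r,
            area=math.pi * r * r,
            perimeter=2.0 * math.pi * r,
        )


@dataclass(frozen=True)
class RectChannel:
    """Rectangular channel with arc-constricted side walls.

    ``W`` is the full channel width, ``H`` the height, ``R_con`` the side-wall
    arc curvature radius and ``W_con`` the throat width.  For ``H`` below the
    8.2 um inlet height, the ceiling/floor taper linearly from ``H_inlet`` to
    ``H`` over ``ramp_start <= x <= ramp_end`` so that the cell is compressed
    before reaching the constriction.
    """

    H: float
    R_con: float = 27.525
    W_con: float = 4.368
    W: float = 22.36
    L: float = 150.0
    delta: float = 0.1
    H_inlet: float = 8.2
    ramp_start: float = -40.17
    ramp_end: float = -35.0

    def __post_init__(self):
        if not (0.0 < self.W_con < self.W):
            raise GeometryError("need 0 < W_con < W")
        if not (0.0 <= self.delta < self.W_con / 2.0):
            raise GeometryError("need delta < W_con/2")
        if self.H <= 2.0 * self.delta:
            raise GeometryError("need H > 2*delta")
        if self.R_con <= 0 or self.L <= 0:
            raise GeometryError("R_con and L must be positive")
        if self.ramp_start >= self.ramp_end:
            raise GeometryError("ramp interval is empty")
        self.half_span(True)

    @property
    def x_outlet(self) -> float:
        return X_INLET + self.L

    @property
    def arc_center_y(self) -> float:
        """Lateral position of the side-wall arc centre."""
        return self.W_con / 2.0 + self.R_con

    def half_span(self, use_imaginary: bool) -> float:
        """Axial half-length of the constricted region of the side walls."""
        d = self.delta if use_imaginary else 0.0
        R = self.R_con + d
        gap = self.arc_center_y - (self.W / 2.0 - d)
        val = R * R - gap * gap
        if val < 0:
            raise GeometryError("side-wall arc does not reach the straight wall")
        return math.sqrt(val)

    def half_width_at(self, x, use_imaginary: bool = False):
        xa = _check_domain(self, x)
        d = self.delta if use_imaginary else 0.0
        R = self.R_con + d
        span = self.half_span(use_imaginary)
        inside = np.abs(xa) < span
        hw = np.where(
            inside,
            self.arc_center_y - np.sqrt(np.maximum(R * R - xa * xa, 0.0)),
            self.W / 2.0 - d,
        )
        return float(hw) if np.isscalar(x) or np.ndim(x) == 0 else hw

    def height_at(self, x, use_imaginary: bool = False):
        xa = _check_domain(self, x)
        if self.H >= self.H_inlet:
            base = np.full_like(xa, self.H, dtype=float)
        else:
            frac = np.clip(
                (xa - self.ramp_start) / (self.ramp_end - self.ramp_start), 0.0, 1.0
            )
            base = self.H_inlet + (self.H - self.H_inlet) * frac
        if use_imaginary:
            base = base - 2.0 * self.delta
        return float(base) if np.isscalar(x) or np.ndim(x) == 0 else base

    def section(self, x, use_imaginary: bool = False) -> LumenSection:
        hw = self.half_width_at(x, use_imaginary)
        h = self.height_at(x, use_imaginary)
        w = 2.0 * hw
        return LumenSection(
            x=float(x),
            half_width=hw,
            height=h,
            area=w * h,
            perimeter=2.0 * (w + h),
        )


# ---------------------------------------------------------------------------
# module-level operations


def axisym_radius_at(channel: AxisymChannel, x, use_imaginary: bool = False):
    """Lumen radius of the axisymmetric channel at axial station ``x``."""
    return channel.radius_at(x, use_imaginary)


def constricted_region_length(channel: AxisymChannel) -> float:
    """Axial length of the constricted region of the imaginary surface.

    26.0 um for the reference capillary.
    """
    return 2.0 * channel.half_span(True)


def rect_half_width_at(channel: RectChannel, x, use_imaginary: bool = False):
    return channel.half_width_at(x, use_imaginary)


def rect_height_at(channel: RectChannel, x, use_imaginary: bool = False):
    return channel.height_at(x, use_imaginary)


def hydraulic_diameter(height: float, width: float) -> float:
    """D_h = 4*area/perimeter = 2*H*W/(H+W) for a rectangular lumen."""
    if height <= 0 or width <= 0:
        raise GeometryError("dimensions must be positive")
    return 2.0 * height * width / (height + width)


def equal_area_width(H: float, r_min: float) -> float:
    """Throat width giving the same cross-sectional area as a circle of
    radius ``r_min`` in a channel of height ``H`` (pi r^2 / H)."""
    if H <= 0:
        raise GeometryError("H must be positive")
    return math.pi * r_min * r_min / H

def equal_dh_width(H: float, d_target: float) -> float:
    """Throat width giving hydraulic diameter ``d_target`` at height ``H``."""
    if H <= 0 or d_target <= 0:
        raise GeometryError("dimensions must be positive")
    if 2.0 * H <= d_target:
        raise GeometryError("infeasible: need 2H > d_target")
    return d_target * H / (2.0 * H - d_target)


def squeeze_length(channel: RectChannel | AxisymChannel, R_cell: float) -> FirstContact:
    """First tangency of a sphere of radius ``R_cell`` (centre on the axis)
    with the imaginary side-wall arc.

    The contact condition in the z = 0 midplane is that the distance from the
    sphere centre ``(-s, 0)`` to the arc centre ``(0, Y)`` equals
    ``R_arc + delta + R_cell``, hence

        s = sqrt((R_con + delta + R_cell)^2 - Y^2),  Y = W_con/2 + R_con.
    """
    if isinstance(channel, AxisymChannel):
        half_opening = channel.r_min
        Y = channel.arc_center_r
        R_arc = channel.r_con
    else:
        half_opening = channel.W_con / 2.0
        Y = channel.arc_center_y
        R_arc = channel.R_con
    if half_opening - channel.delta >= R_cell:
        return FirstContact(s=math.nan, theta=math.nan, contact_exists=False)
    reach = R_arc + channel.delta + R_cell
    s = math.sqrt(max(reach * reach - Y * Y, 0.0))
    theta = math.atan2(Y, s)
    return FirstContact(s=s, theta=theta, contact_exists=True)


def contact_angle_first_contact(
    channel: RectChannel | AxisymChannel, R_cell: float
) -> float:
    """Contact angle at first side-wall tangency; pi/2 when tangency occurs
    exactly at the throat."""
    fc = squeeze_length(channel, R_cell)
    if not fc.contact_exists:
        raise GeometryError("cell does not contact the constriction")
    return fc.theta
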