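"""Reduced-order family of deformed cell shapes.

The squeezed cell is represented by a capsule-like body: an ellipsoidal
axial profile g(u) = sqrt(1 - u^2), u = xi/c, scaled onto a
rectangle-with-rounded-corners cross-section of lateral half-extent
``w*g``, vertical half-extent ``h*g`` and corner fillet radius
``min(r_fillet, min(w, h)*g)``.  With ``w == h`` and a full fillet the
cross-section degenerates to a circle and the body to a sphere/spheroid,
so the undeformed cell is a member of the family.

The corner fillet is what leaves the gutters — the corner clearances of
the rectangular channel through which plasma leaks past the cell.  Its
radius is set by the cortical tension (Laplace: r ~ T_c / driving stress).

Volume is available in closed form, which lets the simulator conserve the
cell volume exactly by solving for the axial semi-length ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CellShape", "section_area", "shape_volume", "solve_c", "solve_free"]

_FMP = 4.0 - math.pi


@dataclass(frozen=True)
class CellShape:
    """Deformed-cell geometry: half-extents ``w`` (lateral), ``h``
    (vertical), axial semi-length ``c`` and corner fillet ``r_fillet``."""

    w: float
    h: float
    c: float
    r_fillet: float

    @property
    def body_length(self) -> float:
        return 2.0 * self.c


def section_area(w: float, h: float, r_fillet: float, u: float | np.ndarray = 0.0):
    """Cross-section area at relative axial station ``u`` in [-1, 1]."""
    g2 = np.clip(1.0 - np.square(u), 0.0, None)
    g = np.sqrt(g2)
    r = np.minimum(r_fillet, min(w, h) * g)
    return 4.0 * w * h * g2 - _FMP * r * r


def _profile_integral(w: float, h: float, r_fillet: float) -> float:
    """I such that the body volume is c * I (closed form).

    Splits the axial integral at u* where the fillet saturates at
    min(w, h)*g(u*)."""
    m = min(w, h)
    rc = min(r_fillet, m)
    if rc >= m - 1e-15:
        return (4.0 * w * h - _FMP * m * m) * (4.0 / 3.0)
    ustar = math.sqrt(max(1.0 - (rc / m) ** 2, 0.0))
    inner = 4.0 * w * h * 2.0 * (ustar - ustar ** 3 / 3.0) - _FMP * rc * rc * 2.0 * ustar
    outer = (4.0 * w * h - _FMP * m * m) * 2.0 * (2.0 / 3.0 - ustar + ustar ** 3 / 3.0)
    return inner + outer


def shape_volume(shape: CellShape) -> float:
    """Exact volume of the shape."""
    return shape.c * _profile_integral(shape.w, shape.h, shape.r_fillet)


def solve_c(w: float, h: float, r_fillet: float, volume: float) -> float:
    """Axial semi-length conserving ``volume`` at given cross-section."""
    return volume / _profile_integral(w, h, r_fillet)


def solve_free(
    w: float, r_fillet: float, volume: float, h_cap: float,
    h_guess: float | None = None,
) -> tuple[float, float]:
    """Vertical half-extent and axial semi-length for a laterally squeezed
    cell that expands freely (and equally, h == c) in the unconstrained
    directions, capped by the ceiling/floor at ``h_cap``.

    Returns ``(h, c)`` with exact volume conservation.
    """
    # solve h * I(w, h) == volume with c == h (monotone in h); Newton with
    # a bisection fallback
    h = h_guess if h_guess and h_guess > 0 else math.sqrt(
        volume / (max(w, 1e-6) * 4.19))
    f = lambda x: x * _profile_integral(w, x, r_fillet) - volume
    ok = False
    for _ in range(40):
        fx = f(h)
        if abs(fx) < 1e-12 * volume:
            ok = True
            break
        dh = max(1e-7, 1e-7 * h)
        deriv = (f(h + dh) - fx) / dh
        if deriv <= 0:
            break
        h_new = h - fx / deriv
        if h_new <= 0:
            h_new = 0.5 * h
        h = h_new
    if not ok:
        lo, hi = 1e-3, max(8.0 * w, (volume / max(w, 1e-6)) ** 0.5, 4.0)
        while f(hi) < 0:
            hi *= 2.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        h = 0.5 * (lo + hi)
    if h > h_cap:
        return h_cap, solve_c(w, h_cap, r_fillet, volume)
    return h, h
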