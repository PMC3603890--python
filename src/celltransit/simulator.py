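"""Reduced-order quasi-static simulation of cell transit.

The 3-D fluid-structure interaction is collapsed onto a small set of
degrees of freedom: the cell's axial position, one lateral and one
vertical squeeze extent (each an effective scalar strain of a Maxwell
element), and a volume-conserving capsule shape (:mod:`celltransit.shapes`).
Each time step is quasi-static:

1. contact of the capsule with the imaginary side walls limits how far the
   cell may advance (first tangency, resolved by bisection);
2. the pressure drop across the occluded span follows from the
   series-parallel resistance network of :mod:`celltransit.leakage`;
3. the excess of that pressure drop over the Law-of-Laplace critical
   pressure, redirected laterally by the contact angle (force balance on
   the frictionless arc: lateral/axial = tan(theta)), drives the Maxwell
   element — an instantaneous elastic deflection plus viscous creep;
4. vertical extent and body length follow from exact volume conservation,
   with the ceiling/floor acting as a rigid cap;
5. the cell advances to the new tangency position, no faster than the
   local plug-flow velocity of the plasma.

The transit time is the period between the two axial-velocity peaks: the
one just before side-wall contact and the one at expulsion through the
throat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .geometry import AxisymChannel, RectChannel, X_INLET
from .leakage import (
    Gutter,
    GutterNetwork,
    Plasma,
    gutter_conductance,
    open_channel_resistance,
    pressure_partition,
)
from .rheology import CellModel, MaxwellState, critical_pressure
from .shapes import CellShape, section_area, shape_volume, solve_c, solve_free

__all__ = [
    "ModelParams",
    "CellState",
    "TransitRecord",
    "TransitSimulator",
    "cell_shape",
    "step",
    "simulate_transit",
    "detect_velocity_peaks",
    "transit_time",
    "PeakDetectionError",
]


class PeakDetectionError(RuntimeError):
    """Fewer than two qualifying velocity peaks: no transit time defined."""


class ShapeInfeasibleError(ValueError):
    """The cell volume cannot be accommodated by the shape family."""


@dataclass(frozen=True)
class ModelParams:
    """Tunable constants of the reduced-order model.

    ``squeeze_efficiency`` is the fraction of the plugging force converted
    into effective deviatoric lateral stress (lumps the projection factors
    of the real traction distribution); ``tan_theta_cap`` regularises the
    contact force balance at the throat where the wall normal is purely
    lateral; ``gutter_shape_factor`` is the duct shape factor of the
    bypass conduits.
    """

    squeeze_efficiency: float = 0.25
    tan_theta_cap: float = 25.0
    gutter_shape_factor: float = 0.5
    tau_elastic: float = 0.01     # s, relaxation of the spring response
    tau_filter: float = 0.005     # s, smoothing of the plug-flux feedback
    drag_blockage_cap: float = 50.0  # cap on the confined-drag multiplier
    x_start: float = -20.0
    peak_prominence_frac: float = 0.05
    n_stations: int = 129
    max_steps: int = 30000
    stall_time: float = 2.0       # s of no usable excess pressure -> stalled
    min_excess: float = 0.05      # Pa, below this counts as stalled
    fillet_floor: float = 0.05    # um, smallest corner fillet


@dataclass
class CellState:
    """Instantaneous reduced state of the cell."""

    x_mid: float
    w_cell: float        # lateral half-extent, um
    h_cell: float        # vertical half-extent, um
    c_body: float        # axial semi-length, um
    r_fillet: float
    eps_v_lat: float = 0.0   # accumulated viscous lateral strain (log)
    eps_e_lat: float = 0.0   # elastic (recoverable) lateral strain
    sigma_lat: float = 0.0   # current lateral driving stress, Pa
    eps_v_vert: float = 0.0
    v: float = 0.0           # axial velocity, um/s
    dP_cell: float = 0.0
    contact_side: bool = False
    contact_cf: bool = False  # ceiling/floor contact

    @property
    def body_length(self) -> float:
        return 2.0 * self.c_body

    @property
    def x_lead(self) -> float:
        return self.x_mid + self.c_body

    @property
    def x_trail(self) -> float:
        return self.x_mid - self.c_body

    @property
    def maxwell_lat(self) -> MaxwellState:
        return MaxwellState(sigma=self.sigma_lat,
                            epsilon=self.eps_v_lat + self.eps_e_lat)

    @property
    def maxwell_vert(self) -> MaxwellState:
        return MaxwellState(sigma=0.0, epsilon=self.eps_v_vert)

    @property
    def contacts(self) -> dict:
        return {"side_walls": self.contact_side, "ceiling_floor": self.contact_cf}

    @property
    def shape(self) -> CellShape:
        return CellShape(self.w_cell, self.h_cell, self.c_body, self.r_fillet)


def cell_shape(state: CellState) -> CellShape:
    """Parametric capsule shape of the current state (volume, contact and
    gutter geometry all derive from it)."""
    return state.shape


@dataclass
class TransitRecord:
    """Time series of one transit plus the detected velocity peaks."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    dP_cell: np.ndarray
    w: np.ndarray
    h: np.ndarray
    c: np.ndarray
    r_fillet: np.ndarray
    contact_side: np.ndarray
    contact_cf: np.ndarray
    gutter_conductance: np.ndarray
    gutters_united: np.ndarray
    completed: bool
    stalled: bool = False
    peaks: np.ndarray | None = None
    T: float | None = None


def detect_velocity_peaks(record: TransitRecord, prominence_frac: float = 0.05):
    """Indices of the first and last velocity peaks with prominence at
    least ``prominence_frac`` of the maximum velocity (earliest index on
    ties, which find_peaks resolves by construction)."""
    v = np.asarray(record.v, dtype=float)
    if v.size < 3:
        raise PeakDetectionError("need at least 3 samples")
    vmax = float(np.max(v))
    if vmax <= 0:
        raise PeakDetectionError("no positive velocities")
    idx, _ = find_peaks(v, prominence=prominence_frac * vmax)
    if idx.size < 2:
        raise PeakDetectionError("fewer than two velocity peaks")
    return idx


def transit_time(record: TransitRecord, prominence_frac: float = 0.05) -> float:
    """Transit time: period between the first and last velocity peaks."""
    idx = detect_velocity_peaks(record, prominence_frac)
    return float(record.t[idx[-1]] - record.t[idx[0]])


# ---------------------------------------------------------------------------


class TransitSimulator:
    """Holds the per-run context and advances the quasi-static state."""

    def __init__(
        self,
        channel,
        cell: CellModel | None = None,
        plasma: Plasma | None = None,
        dP_total: float = 40.0,
        dt: float = 1e-3,
        params: ModelParams | None = None,
    ):
        self.channel = channel
        self.cell = cell or CellModel()
        self.plasma = plasma or Plasma()
        self.dP_total = float(dP_total)
        self.dt = float(dt)
        self.p = params or ModelParams()
        self.axisym = isinstance(channel, AxisymChannel)

        self.V0 = self.cell.volume
        if self.axisym:
            self.Y = channel.arc_center_r
            self.a_throat = channel.r_min - channel.delta
            self.span_end = channel.half_span(True)
        else:
            self.Y = channel.arc_center_y
            self.a_throat = channel.W_con / 2.0 - channel.delta
            self.span_end = channel.half_span(True)
        if self.a_throat <= 0:
            raise ShapeInfeasibleError("imaginary throat closed")

        # effective opening the cell must creep into: imaginary throat,
        # height clipped to the free deformed-cell height
        if self.axisym:
            self.r_open = self.a_throat
            self.h_star = None
        else:
            h_im_throat = channel.height_at(0.0, True)
            h_star, _ = solve_free(self.a_throat, 1.0, self.V0, 1e9)
            self.h_star = h_star
            h_open = min(h_im_throat, 2.0 * h_star)
            w_open = 2.0 * self.a_throat
            self.r_open = h_open * w_open / (h_open + w_open)  # D_h/2
        self.dP_crit = critical_pressure(self.cell, min(self.r_open, self.cell.R_cell))
        self._last_contact_x = 0.0
        self._last_excess = float("inf")

        r_tot = open_channel_resistance(channel, X_INLET, channel.x_outlet, self.plasma)
        self.Q_open = self.dP_total / r_tot if r_tot > 0 else 0.0

        self._u = np.linspace(-1.0, 1.0, self.p.n_stations)

    # -- geometry helpers ---------------------------------------------------

    def _lumen_half_width_im(self, xs):
        xs = np.clip(xs, X_INLET, self.channel.x_outlet)
        if self.axisym:
            return self.channel.radius_at(xs, True)
        return self.channel.half_width_at(xs, True)

    def _lumen_area_im(self, xs):
        xs = np.clip(xs, X_INLET, self.channel.x_outlet)
        if self.axisym:
            r = self.channel.radius_at(xs, True)
            return math.pi * r * r
        hw = self.channel.half_width_at(xs, True)
        h = self.channel.height_at(xs, True)
        return 2.0 * hw * h

    def _lumen_area_actual(self, x):
        x = min(max(x, X_INLET), self.channel.x_outlet)
        return self.channel.section(x, False).area

    def min_side_clearance(self, x_mid: float, shape: CellShape) -> float:
        """Smallest gap between the cell surface and the imaginary side
        wall along the body (parabolic refinement of the grid minimum)."""
        u = self._u
        xs = x_mid + shape.c * u
        wall = self._lumen_half_width_im(xs)
        cellw = shape.w * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
        clear = wall - cellw
        i = int(np.argmin(clear))
        self._last_contact_x = float(xs[i])
        best = float(clear[i])
        if 0 < i < u.size - 1:
            y0, y1, y2 = clear[i - 1], clear[i], clear[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom > 0:
                du = 0.5 * (y0 - y2) / denom * (u[1] - u[0])
                ur = u[i] + du
                if -1.0 < ur < 1.0:
                    xr = x_mid + shape.c * ur
                    cw = shape.w * math.sqrt(max(1.0 - ur * ur, 0.0))
                    best = min(best, float(self._lumen_half_width_im(xr) - cw))
        return best

    def _max_feasible_x(self, x_lo: float, x_hi: float, shape: CellShape) -> float:
        """Largest x in [x_lo, x_hi] with non-negative side clearance."""
        if self.min_side_clearance(x_hi, shape) >= 0.0:
            return x_hi
        # ensure a feasible lower bracket
        guard = 0
        while self.min_side_clearance(x_lo, shape) < 0.0 and guard < 60:
            x_lo -= 0.02
            guard += 1
        if guard >= 60:
            return x_lo  # degenerate; caller treats as stalled contact
        lo, hi = x_lo, x_hi
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if self.min_side_clearance(mid, shape) >= 0.0:
                lo = mid
            else:
                hi = mid
        return lo

    def _local_crit(self, x_contact: float) -> float:
        """Law-of-Laplace entry pressure against the local opening at the
        contact point; grows toward the throat value as the cell wedges in."""
        a_loc = float(self._lumen_half_width_im(np.array([x_contact]))[0])
        if self.axisym:
            r_loc = a_loc
        else:
            h_open = min(self.channel.height_at(x_contact, True),
                         2.0 * self.h_star)
            w_loc = 2.0 * a_loc
            r_loc = w_loc * h_open / (w_loc + h_open)
        r_loc = min(r_loc, self.cell.R_cell)
        return critical_pressure(self.cell, r_loc)

    def _h_cap(self, x_mid: float) -> float:
        if self.axisym:
            return float("inf")
        return self.channel.height_at(x_mid, True) / 2.0

    def _resolve_shape(self, w: float, r_f: float, x_mid: float):
        """Vertical extent and body length at given lateral extent, with
        exact volume conservation."""
        if self.axisym:
            # axisymmetric squeeze: h tied to w, circular cross-section
            c = solve_c(w, w, w, self.V0)
            return w, c, w
        h, c = solve_free(w, r_f, self.V0, self._h_cap(x_mid))
        return h, c, r_f

    def _shape_from_dh(self, d_h: float, r_f: float, x_mid: float,
                       h_guess: float) -> CellShape:
        """Shape whose mid cross-section has hydraulic diameter ``d_h``.

        The Maxwell strain acts on the cross-section hydraulic diameter —
        the squeeze measure the two channel families share — and the
        width/height split follows from the ceiling cap plus free (equal
        vertical/axial) expansion with exact volume conservation.
        """
        if self.axisym:
            w = d_h / 2.0
            c = solve_c(w, w, w, self.V0)
            return CellShape(w, w, c, w)
        # D_h of the mid cross-section is monotone increasing in w on the
        # squeeze branch; bisect w
        cap = self._h_cap(x_mid)
        h_prev = h_guess

        def props(w):
            nonlocal h_prev
            h, c = solve_free(w, min(r_f, w), self.V0, cap, h_guess=h_prev)
            h_prev = h
            return h, c

        lo = d_h / 4.0 + 1e-9
        hi = self.w_ref + 0.5
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            h, _ = props(mid)
            if 4.0 * mid * h / (mid + h) < d_h:
                lo = mid
            else:
                hi = mid
        w = 0.5 * (lo + hi)
        h, c = props(w)
        return CellShape(w, h, c, min(r_f, w))

    # -- hydraulics ---------------------------------------------------------

    def _network_and_span(self, state: CellState):
        """Gutter network and occluded span from the current shape."""
        shape = state.shape
        u = np.linspace(-1.0, 1.0, 33)
        xs = state.x_mid + shape.c * u
        a_cell = section_area(shape.w, shape.h, shape.r_fillet, u)
        a_lum = self._lumen_area_im(xs)
        occ = a_cell > 0.5 * a_lum
        if not np.any(occ):
            mid = slice(u.size // 4, 3 * u.size // 4)
            occ = np.zeros_like(occ)
            occ[mid] = True
        x_lo = float(xs[occ][0])
        x_hi = float(xs[occ][-1])
        if x_hi - x_lo < 0.5:
            x_lo, x_hi = state.x_mid - 0.25, state.x_mid + 0.25
        gap = np.where(occ, a_lum - a_cell, np.inf)
        i_t = int(np.argmin(gap))
        a_byp = max(float(a_lum[i_t] - a_cell[i_t]), 0.0)

        if self.axisym:
            network = GutterNetwork(gutters=(), united=False)
        else:
            h_cap = self._h_cap(state.x_mid)
            cf_contact = state.h_cell >= h_cap - 1e-9
            g_t = math.sqrt(max(1.0 - u[i_t] ** 2, 0.0))
            if cf_contact:
                r_t = max(min(shape.r_fillet, min(shape.w, shape.h) * g_t),
                          1e-3)
                per = (2.0 + math.pi / 2.0) * r_t
                gutters = tuple(Gutter(a_byp / 4.0, per) for _ in range(4))
                network = GutterNetwork(gutters=gutters, united=False)
            else:
                t_gap = max(h_cap - shape.h, 1e-3)
                width = 2.0 * float(self._lumen_half_width_im(xs[i_t]))
                per = 2.0 * (width + t_gap)
                gutters = tuple(Gutter(a_byp / 2.0, per) for _ in range(2))
                network = GutterNetwork(gutters=gutters, united=True)
        return network, (x_lo, x_hi)

    # -- stepping -----------------------------------------------------------

    def initial_state(self) -> CellState:
        R = self.cell.R_cell
        x0 = self.p.x_start
        h_cap = self._h_cap(x0)
        if h_cap >= R:
            st = CellState(x_mid=x0, w_cell=R, h_cell=R, c_body=R, r_fillet=R)
        else:
            # pre-compressed by the ceiling/floor: stadium cross-section,
            # equal lateral/axial extents, exact volume
            lo, hi = h_cap, 4.0 * R
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                sh = CellShape(mid, h_cap, mid, h_cap)
                if shape_volume(sh) < self.V0:
                    lo = mid
                else:
                    hi = mid
            w0 = 0.5 * (lo + hi)
            # the inlet ramp is crossed in milliseconds, far below the
            # Maxwell relaxation time: the pre-compression is stored
            # elastically, not as relaxed (viscous) strain
            d_init = 4.0 * w0 * h_cap / (w0 + h_cap)
            eps_e0 = math.log(2.0 * R / d_init)
            st = CellState(
                x_mid=x0, w_cell=w0, h_cell=h_cap, c_body=w0, r_fillet=h_cap,
                eps_e_lat=eps_e0,
                sigma_lat=self.cell.G_cell * eps_e0,
                eps_v_vert=math.log(R / h_cap),
            )
        self.w_ref = st.w_cell
        self.D0 = 2.0 * R
        self._v_plug = self._v_free(x0)
        return st

    def _v_free(self, x: float) -> float:
        return self.Q_open / self._lumen_area_actual(x)

    def _filter_v(self, v: float) -> None:
        a = 1.0 - math.exp(-self.dt / self.p.tau_filter)
        self._v_plug += (v - self._v_plug) * a

    def step(self, state: CellState) -> CellState:
        """One quasi-static update; returns the new state."""
        p, dt = self.p, self.dt
        cellm = self.cell
        x = state.x_mid
        v_free = self._v_free(x)
        cand = x + v_free * dt
        shape = state.shape

        if self.min_side_clearance(cand, shape) >= 0.0:
            # free advection: no side contact limits the advance; elastic
            # recovery proceeds as far as the walls allow (bisected so the
            # cell stays tangent while leaving the constriction)
            sigma = state.sigma_lat * math.exp(-dt / cellm.relaxation_time)
            blend = 1.0 - math.exp(-dt / p.tau_elastic)
            eps_e = state.eps_e_lat + (sigma / cellm.G_cell - state.eps_e_lat) * blend
            eps_v = state.eps_v_lat + sigma / cellm.mu_cell * dt
            eps = eps_v + eps_e
            d_t = self.D0 * math.exp(-eps)
            r_f = min(state.r_fillet * 1.5 + 0.05, d_t / 2.0)

            def shape_at(d):
                return self._shape_from_dh(d, r_f, cand, shape.h)

            trial = shape_at(d_t)
            if self.min_side_clearance(cand, trial) < 0.0:
                d_cur = 4.0 * shape.w * shape.h / (shape.w + shape.h)
                lo, hi = d_cur, d_t  # current section fits, target does not
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if self.min_side_clearance(cand, shape_at(mid)) >= 0.0:
                        lo = mid
                    else:
                        hi = mid
                trial = shape_at(lo)
            new_shape = trial
            self._filter_v(v_free)
            return replace(
                state,
                x_mid=cand,
                w_cell=new_shape.w,
                h_cell=new_shape.h,
                c_body=new_shape.c,
                r_fillet=new_shape.r_fillet,
                eps_v_lat=eps_v,
                eps_e_lat=eps_e,
                sigma_lat=sigma,
                v=v_free,
                dP_cell=float("nan"),
                contact_side=False,
                contact_cf=new_shape.h >= self._h_cap(cand) - 1e-9,
            )

        # squeezing phase -------------------------------------------------
        self.min_side_clearance(x, shape)  # sets the contact point
        dP_crit = self._local_crit(self._last_contact_x)
        network, span = self._network_and_span(state)
        a_front = min(
            section_area(shape.w, shape.h, shape.r_fillet, 0.0),
            float(self._lumen_area_im(np.array([x]))[0]),
        )
        dP_ref = state.dP_cell if (state.contact_side and
                                   math.isfinite(state.dP_cell)) else self.dP_total
        g_plug = a_front * self._v_plug / max(dP_ref, 1e-9)
        network = replace(network, plug_conductance=g_plug)
        self._last_g_gutter = gutter_conductance(
            network, max(span[1] - span[0], 1e-9), self.plasma,
            k=p.gutter_shape_factor,
        ) if network.gutters else 0.0
        self._last_united = network.united
        dP_cell = pressure_partition(
            self.dP_total, span, self.channel, network, self.plasma,
            k=p.gutter_shape_factor,
        )
        excess = dP_cell - dP_crit

        # confined Stokes drag of the plasma streaming past a cell that does
        # not seal the lumen; the open-segment flux consistent with the
        # partition makes this vanish automatically once the cell plugs
        r_open_seg = (
            open_channel_resistance(self.channel, X_INLET, span[0], self.plasma)
            + open_channel_resistance(self.channel, span[1],
                                      self.channel.x_outlet, self.plasma)
        )
        q_act = max(self.dP_total - dP_cell, 0.0) / max(r_open_seg, 1e-12)
        a_lum_here = float(self._lumen_area_im(np.array([x]))[0])
        u_loc = q_act / self._lumen_area_actual(x)
        blockage = min(a_front / a_lum_here, 0.95)
        k_conf = min((1.0 - blockage) ** -2, p.drag_blockage_cap)
        f_drag = k_conf * 6.0 * math.pi * self.plasma.mu_p * self.cell.R_cell \
            * max(u_loc - max(state.v, 0.0), 0.0)

        f_net = max(excess * a_front + f_drag, 0.0)
        self._last_excess = f_net / max(a_front, 1e-9)

        tan_theta = min(self.Y / max(abs(min(x, -1e-9)), 1e-9), p.tan_theta_cap)
        if x >= 0:
            tan_theta = p.tan_theta_cap
        a_ymid = math.pi * shape.c * shape.h
        sigma = p.squeeze_efficiency * f_net * tan_theta / a_ymid
        eps_v = state.eps_v_lat + sigma / cellm.mu_cell * dt
        blend = 1.0 - math.exp(-dt / p.tau_elastic)
        eps_e = state.eps_e_lat + (sigma / cellm.G_cell - state.eps_e_lat) * blend
        eps = eps_v + eps_e
        d_cur = 4.0 * shape.w * shape.h / (shape.w + shape.h)
        d_new = max(self.D0 * math.exp(-eps), 0.5 * self.a_throat)
        d_new = min(d_new, d_cur + 1e-12)  # squeeze never widens here
        r_target = max(cellm.T_c / max(excess, 0.5), p.fillet_floor)
        r_f = state.r_fillet + (r_target - state.r_fillet) * blend
        new_shape = self._shape_from_dh(d_new, r_f, x, shape.h)
        if new_shape.w > state.w_cell:
            # the wall blocks any widening; project onto the feasible width
            w_clamp = state.w_cell
            h_cl, c_cl, r_cl = self._resolve_shape(w_clamp,
                                                   min(r_f, w_clamp), x)
            new_shape = CellShape(w_clamp, h_cl, c_cl, min(r_f, w_clamp))
        w_new, h_new, c_new, r_f = (new_shape.w, new_shape.h, new_shape.c,
                                    new_shape.r_fillet)

        x_new = self._max_feasible_x(x, cand, new_shape)
        v = (x_new - x) / dt
        self._filter_v(max(v, 0.0))
        return replace(
            state,
            x_mid=x_new,
            w_cell=w_new,
            h_cell=h_new,
            c_body=c_new,
            r_fillet=r_f,
            eps_v_lat=eps_v,
            eps_e_lat=eps_e,
            sigma_lat=sigma,
            v=v,
            dP_cell=dP_cell,
            contact_side=True,
            contact_cf=h_new >= self._h_cap(x_new) - 1e-9,
        )

    def run(self) -> TransitRecord:
        p = self.p
        state = self.initial_state()
        rows = []
        stall = 0
        completed = False
        stalled = False
        t = 0.0
        for _ in range(p.max_steps):
            self._last_g_gutter = 0.0
            self._last_united = False
            state = self.step(state)
            t += self.dt
            rows.append(
                (
                    t, state.x_mid, state.v, state.dP_cell, state.w_cell,
                    state.h_cell, state.c_body, state.r_fillet,
                    state.contact_side, state.contact_cf,
                    self._last_g_gutter, self._last_united,
                )
            )
            if state.contact_side and self._last_excess < p.min_excess:
                stall += 1
                if stall * self.dt > p.stall_time:
                    stalled = True
                    break
            else:
                stall = 0
            if state.x_trail > self.span_end + 1.0:
                completed = True
                break
        arr = np.array(rows, dtype=float)
        rec = TransitRecord(
            t=arr[:, 0], x=arr[:, 1], v=arr[:, 2], dP_cell=arr[:, 3],
            w=arr[:, 4], h=arr[:, 5], c=arr[:, 6], r_fillet=arr[:, 7],
            contact_side=arr[:, 8].astype(bool),
            contact_cf=arr[:, 9].astype(bool),
            gutter_conductance=arr[:, 10],
            gutters_united=arr[:, 11].astype(bool),
            completed=completed, stalled=stalled,
        )
        try:
            idx = detect_velocity_peaks(rec, p.peak_prominence_frac)
            rec.peaks = idx
            rec.T = float(rec.t[idx[-1]] - rec.t[idx[0]])
        except PeakDetectionError:
            rec.peaks = np.array([], dtype=int)
            rec.T = None
        return rec


def step(state, channel, cell, plasma, dP_total, dt, params=None):
    """Single quasi-static update (module-level convenience wrapper)."""
    sim = TransitSimulator(channel, cell, plasma, dP_total, dt, params)
    sim.w_ref = getattr(state, "_w_ref", state.w_cell)
    d_cur = 4.0 * state.w_cell * state.h_cell / (state.w_cell + state.h_cell)
    sim.D0 = d_cur * math.exp(state.eps_v_lat + state.eps_e_lat)
    sim._v_plug = max(state.v, 0.0) if state.v else sim._v_free(state.x_mid)
    return sim.step(state)


def simulate_transit(
    channel,
    cell: CellModel | None = None,
    plasma: Plasma | None = None,
    dP_total: float = 40.0,
    dt: float = 1e-3,
    params: ModelParams | None = None,
) -> TransitRecord:
    """Simulate one full transit and return its record.

    The cell starts spherical (or ceiling/floor pre-compressed in shallow
    channels), centred on the axis at ``params.x_start``; integration runs
    until the trailing end clears the constricted region or the step
    budget is exhausted.
    """
    return TransitSimulator(channel, cell, plasma, dP_total, dt, params).run()
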