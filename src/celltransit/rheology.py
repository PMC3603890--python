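"""Neutrophil constitutive behaviour.

The cell interior is a linear Maxwell liquid (spring ``G_cell`` and dashpot
``mu_cell`` in series, relaxation time ``lambda = mu_cell/G_cell``) wrapped in
a membrane under constant cortical tension ``T_c``.  The cortical tension
sets the Law-of-Laplace critical pressure for entry into a narrow opening;
the Maxwell element gives the instantaneous elastic deformation on first
contact followed by slow viscous creep.

Units: stresses in Pa, tension in pN/um (numerically equal to Pa*um),
lengths in um, time in s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "CellModel",
    "MaxwellState",
    "ContactBand",
    "relaxation_time",
    "maxwell_update",
    "critical_pressure",
    "reaction_stress",
]

#: cap on tan(theta) used when resolving the contact force balance near the
#: throat, where the wall normal becomes purely lateral and the axial
#: component of the reaction vanishes.
TAN_THETA_CAP = 25.0


@dataclass(frozen=True)
class CellModel:
    """Rheological and geometric parameters of the neutrophil.

    Defaults are the cell-poking / micropipette-aspiration values:
    interior viscosity 31 Pa*s, shear modulus 186 Pa, cortical tension
    31 pN/um, resting radius 4 um.  Poisson ratio and the membrane modulus/
    thickness are recorded for fidelity but unused by the reduced-order
    model (incompressibility is imposed exactly, membrane bending neglected).
    """

    mu_cell: float = 31.0          # Pa*s
    G_cell: float = 186.0          # Pa
    T_c: float = 31.0              # pN/um == Pa*um
    R_cell: float = 4.0            # um
    nu: float = 0.4999             # recorded only
    E_mem: float = 1e-4            # Pa, recorded only
    h_mem: float = 1.0             # nm, recorded only

    def __post_init__(self):
        if min(self.mu_cell, self.G_cell, self.T_c, self.R_cell) <= 0:
            raise ValueError("cell parameters must be positive")

    @property
    def relaxation_time(self) -> float:
        return self.mu_cell / self.G_cell

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.R_cell ** 3


@dataclass(frozen=True)
class MaxwellState:
    """State of one scalar Maxwell element: deviatoric stress and
    accumulated total strain."""

    sigma: float = 0.0
    epsilon: float = 0.0


def relaxation_time(cell: CellModel) -> float:
    """Maxwell relaxation time mu_cell/G_cell in seconds."""
    return cell.relaxation_time


def maxwell_update(
    state: MaxwellState, strain_rate: float, dt: float, cell: CellModel
) -> MaxwellState:
    """Advance the Maxwell element sigma + lambda*sigma_dot = mu*eps_dot.

    Uses the exponential update, exact for a strain rate held constant over
    the step and unconditionally stable:

        sigma(t+dt) = sigma(t) e^{-dt/lambda} + mu*eps_dot (1 - e^{-dt/lambda})
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = cell.relaxation_time
    decay = math.exp(-dt / lam)
    sigma = state.sigma * decay + cell.mu_cell * strain_rate * (1.0 - decay)
    return replace(state, sigma=sigma, epsilon=state.epsilon + strain_rate * dt)


def critical_pressure(cell: CellModel, r_throat: float) -> float:
    """Law-of-Laplace critical aspiration pressure 2 T_c (1/r - 1/R_cell).

    Minimum pressure drop for a cortical-tension drop to flow into an
    opening of effective radius ``r_throat``; zero when the opening is as
    wide as the cell.  With T_c in pN/um and radii in um the result is Pa.
    """
    if r_throat <= 0:
        raise ValueError("r_throat must be positive")
    if r_throat > cell.R_cell:
        warnings.warn(
            "opening wider than the cell: no plugging, critical pressure 0",
            stacklevel=2,
        )
        return 0.0
    return 2.0 * cell.T_c * (1.0 / r_throat - 1.0 / cell.R_cell)


@dataclass(frozen=True)
class ContactBand:
    """Ring/band of elastically deformed cell in contact with the wall."""

    l: float                 # axial width of the band, um
    theta: float             # contact angle, rad
    r_contact: float         # lateral/radial position of the band centre, um
    tau: float = 0.0         # normal reaction stress, Pa


def reaction_stress(
    dP: float, dP_crit: float, band: ContactBand, r_min: float
) -> float:
    """Normal reaction stress on the contact band of a plugged cell.

    Axial force balance: the excess driving force (dP - dP_crit) * pi r_min^2
    is carried by the axial component of the normal contact stress acting on
    the band of area 2 pi r_contact l, whose normal is elevated by the
    contact angle theta from the x-axis:

        tau * cos(theta) * 2 pi r_contact l = (dP - dP_crit) * pi r_min^2.

    The lateral (squeezing) component is tau*sin(theta) and therefore grows
    with theta — this is the contact-angle mechanism by which wider throats
    and larger curvature radii squeeze the cell harder.  cos(theta) is
    floored (tan(theta) capped at ``TAN_THETA_CAP``) because at the throat
    the wall is parallel to the axis and the balance degenerates.
    """
    if band.l <= 0:
        raise ValueError("undefined contact: band width l must be positive")
    if not (0.0 < band.theta <= math.pi / 2.0 + 1e-12):
        raise ValueError("theta must lie in (0, pi/2]")
    excess = max(dP - dP_crit, 0.0)
    cos_floor = 1.0 / math.sqrt(1.0 + TAN_THETA_CAP ** 2)
    cos_t = max(math.cos(band.theta), cos_floor)
    return excess * r_min * r_min / (2.0 * band.r_contact * band.l * cos_t)
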