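# Methods

`celltransit` is a reduced-order model of a neutrophil passing through a
moderately constricted microchannel — either an axisymmetric arc-shaped
constriction in a cylindrical pipe (the tube-flow idealisation of an
alveolar capillary segment) or a rectangular channel whose side walls carry
arc constrictions (the sheet-flow / photolithography counterpart). The
package deliberately replaces a full 3-D finite-element fluid–structure
simulation with a quasi-static lumped model: the mechanism-level claims the
model is meant to reproduce (squeeze length and contact angle, Laplace
critical pressure, corner-gutter leakage, hydraulic-diameter collapse,
power-law scaling with the constriction curvature radius) are all
expressible at this level, while exact finite-element transit times are not
a goal of this artifact.

## Cell model

The cell interior is a linear Maxwell liquid: spring `G_cell` and dashpot
`mu_cell` in series, `sigma + lambda*sigma_dot = mu_cell*eps_dot`, with
relaxation time `lambda = mu_cell/G_cell`. Default parameters are the
cell-poking / micropipette values: `mu_cell = 31 Pa s`, `G_cell = 186 Pa`
(`lambda = 0.167 s`), constant cortical tension `T_c = 31 pN/um`, resting
radius `R_cell = 4 um`. Poisson ratio (0.4999) and the membrane modulus and
thickness (1e-4 Pa, 1 nm) are recorded on the `CellModel` for fidelity but
unused: incompressibility is imposed exactly through the shape family, and
membrane bending is neglected (it matters only for sub-micron openings).

The Maxwell element is integrated with the exponential update
`sigma(t+dt) = sigma e^{-dt/lambda} + mu*eps_dot (1 - e^{-dt/lambda})`,
exact for a strain rate held constant over the step and unconditionally
stable; it reproduces the closed-form relaxation and creep solutions to
better than 1e-6 at any step size for which the forcing is resolved.

## Geometry

Axial coordinate `x` has the throat at 0 and the inlet at -50 um. Both
channels carry an *imaginary wall*, a contact surface offset
`delta = 0.1 um` into the lumen on which the cell slides frictionlessly
while plasma penetrates it (inherited from the finite-element original,
where it prevents element collapse; retained here because the printed
geometric quantities — the 2.75 um imaginary throat radius, the 26 um
constricted-region length, the 10.8 um squeeze length — are all properties
of the offset surface). The offset is a normal offset: the constriction-arc
radius grows by `delta` about an unchanged centre, flat walls move in by
`delta`. Matched throat widths (equal area `pi r^2/H`, equal hydraulic
diameter `dH/(2H-d)`) use nominal dimensions, which is what reproduces the
printed 3.112/4.368/4.717/3.955 um values.

For channel heights below the 8.2 um inlet height, the ceiling and floor
taper linearly over `-40.17 <= x <= -35 um`; the source only says the
height "gradually decreased", and a linear taper is the simplest consistent
shape. The simulator starts the cell downstream of the ramp, so results are
insensitive to the taper law.

First contact of the spherical cell with the offset side-wall arc is exact:
`s = sqrt((R_con + delta + R_cell)^2 - (W_con/2 + R_con)^2)`, and the
contact angle is the elevation `theta = atan2(W_con/2 + R_con, s)`.

## Deformed-cell shape family

The squeezed cell is a capsule: an ellipsoidal axial profile
`g(u) = sqrt(1-u^2)` scaled onto a rounded-rectangle cross-section with
lateral half-extent `w`, vertical half-extent `h` and corner fillet radius
`r_f = min(T_c/(driving stress), w, h)` — the Laplace fillet the cortical
tension can sustain. With `w = h` and a full fillet this degenerates to a
sphere. The volume integral is closed-form, so the axial semi-length `c`
conserves the cell volume exactly at every step (the conservation test
holds to machine precision). The corner voids between the fillet and the
rectangular channel corner are precisely the gutters.

The single Maxwell strain acts on the *hydraulic diameter* of the mid
cross-section: `D(t) = D0 e^{-eps(t)}`. The width/height split at a given
`D` follows from the ceiling/floor cap (flat frictionless walls are purely
kinematic constraints) and free, equal vertical/axial expansion otherwise.
This choice encodes the central empirical finding the model targets — that
the magnitude of cell squeezing is characterised by the throat hydraulic
diameter relative to the cell, independent of aspect ratio — and it is what
makes the equal-D_h configurations collapse in transit time. A width-based
strain was tried and spreads the equal-D_h set by ~16%.

In channels shallower than the cell, the inlet compression is stored as
*elastic* strain (with the corresponding stress) rather than relaxed
viscous strain: the cell crosses the ramp in milliseconds, far below
`lambda`, so no creep has occurred. This matters: crediting the
pre-compression as permanent strain makes the shallow equal-D_h
configuration ~13% too fast.

## Hydraulics

Re << 1 throughout: every conduit is a Poiseuille resistor. Open
rectangular sections use the Shah–London friction-factor polynomial
(within ~0.1% of the exact double series); gutters use the duct shape-factor
form `G = k A^3/(mu P^2 L)` with `k = 0.5`, exact for a circular section and
between the slot and circular limits otherwise. The channel with a plugged
cell is a series circuit — open duct upstream, occluded span, open duct
downstream — where the occluded span's conductance is the sum of the gutter
bypass and the plug-advection conductance `A_front*v/dP_cell` (the flux a
moving plug carries). When the cell clears the ceiling and floor
(`H` above the deformed-cell height, 2*h_free ≈ 10.0 um at the control
throat width) the four corner gutters unite into two ceiling/floor
clearances whose conductance grows like the cube of the gap — the mechanism
behind the rising branch of the transit-time-vs-height curve. The 0.1 um
plasma film between imaginary and actual walls is neglected in the bypass
network (conductance ~ film thickness cubed).

## Quasi-static stepping

Each step (default `dt = 1e-3 s`, fixed):

1. **Contact**: the largest feasible advance of the capsule against the
   offset side-wall arc is found by bisection (with parabolic refinement of
   the surface-clearance minimum), bounded above by the local plug-flow
   velocity `Q_open/A(x)`. No contact: free advection.
2. **Pressure partition**: `dP_cell` across the occluded span from the
   resistance network above.
3. **Entry resistance**: the Law-of-Laplace critical pressure
   `2 T_c (1/r_open - 1/R_cell)` evaluated against the *local* opening at
   the contact point, with `r_open = D_h/2` of the opening clipped to the
   free deformed-cell height. The `D_h/2` radius is the mean-curvature
   generalisation of the circular-pipette formula: a cap spanning a
   rectangular opening has principal curvatures `2/W` and `2/H`, and
   `(1/W + 1/H) = 2/D_h`. Using the local opening (which tightens to the
   throat value as the cell wedges in) rather than the final throat is what
   lets a cell in a tall channel begin its entry although the full-throat
   critical pressure exceeds the partitioned drop.
4. **Driving force**: `(dP_cell - dP_crit)*A_front` plus a confined Stokes
   drag `K 6 pi mu_p R_cell (U_loc - v)` of plasma streaming past a cell
   that does not seal the lumen, with `K = (1-blockage)^-2` capped at 50.
   The drag uses the open-segment flux consistent with the partition, so it
   vanishes automatically once the cell plugs. The force is redirected into
   lateral squeeze by the frictionless-wall balance: lateral/axial =
   `tan(theta)`, capped at 25 near the throat where the wall normal becomes
   purely lateral. Dividing by the cell's lateral midplane area
   (`pi c h`) and multiplying by the squeeze efficiency `c_sq = 0.25`
   (a lumped projection factor of the real traction distribution, fixed a
   priori) gives the effective deviatoric stress driving the Maxwell
   element.
5. **Deformation**: viscous strain integrates `sigma/mu_cell`; the spring
   deflection `sigma/G_cell` is applied through a short relaxation time
   `tau_elastic = 10 ms`. Strictly instantaneous application makes the
   capsule's midpoint retreat at contact onset (the body elongates into the
   converging wall faster than tangency allows) and produces a spurious
   velocity peak; the 10 ms regularisation leaves the outcome
   rate-independent and dt-convergent. The realised shape is the projection
   of the strain target onto wall feasibility (the width never widens while
   in contact).
6. **Bookkeeping**: volume-conserving shape resolve, fillet update, and the
   diagnostic record (position, velocity, `dP_cell`, gutter conductance,
   contact flags).

The transit time is the period between the two axial-velocity peaks (local
maxima with prominence at least 5% of the peak velocity, ties broken by
earliest index): one just before side-wall contact, one at expulsion
through the throat. The run ends when the trailing end clears the
constricted region; a run whose driving force stays below threshold for 2 s
is reported stalled, and an exhausted step budget returns a partial record
with `completed = False` (mirroring the breakdown cases of the original
study, for which only a transit-time bracket exists).

## Scenario grids

`scenarios.paper_grid` encodes the study conditions exactly: the control
rectangular channel (H = 8.2, R_con = 27.525, W_con = 4.368 um, dP = 40 Pa,
dt = 1 ms), the height sweep over [7.2, 16.2] um (the grid includes the
printed endpoints and the printed minimum location 10.86 um, filled at
~1 um spacing — only those three values are printed), the throat-width set
{3.112, 4.368, 5.7} um, the curvature-radius set {16.15, 27.525, 42.15} um,
the three equal-hydraulic-diameter aspect-ratio pairs, and the reference
axisymmetric capillary. Random grids for property tests are pure functions
of their seed.

## What the model does and does not reproduce

Reproduced quantitatively (test suite): all printed squeeze lengths and
matched widths at printed precision; the 26 um constricted length and
2.75 um imaginary throat; the critical-pressure values; the printed power
law constants' consequences (0.79 s, 0.77 s, 37.6 um crossing).

Reproduced as trends (test suite): transit time strictly decreasing in
throat width (with a > 3x slowdown at the equal-area width) and in
curvature radius (despite the growing squeeze length; fitted exponent
negative, magnitude ~ -0.9 to -1.0, reported rather than forced); an
interior transit-time minimum in H within [9, 13] um with the descending
branch steeper than the ascending one; equal-D_h configurations within
+-10% of their group mean; the two-peak velocity trace with most of the
transit spent upstream of the throat; straight-region cell velocity above
250 um/s; < 2% change of T under time-step halving.

Not reproduced: absolute finite-element transit times (the quasi-static
model lacks the 3-D pressure field and produces transits a factor ~2-4
faster at the default squeeze efficiency; only ratios and trends are
calibration-robust, which the tests verify), the detailed deformed surface,
and the 10.86 um maximally-deformed-cell height — the shape family's own
free deformed height at the control throat is ~10.0 um and is reported,
not forced. Sudden contractions (R_con -> 0) are outside the model's
validity, as they are for the original.

## Numerical choices

Fixed-step quasi-static integration at dt = 1 ms (halving changes T < 2%);
contact bisection to 1e-12 um with the cell kept on the feasible side;
volume solves by Newton with bisection fallback, exact to machine
precision; peak prominence 5% of max velocity; all simulations are
deterministic — randomness exists only in the synthetic fixtures, which are
pure functions of their seeds. Sweep problem sizes are the study's own
grids (19 configurations), each integrating a few hundred to a few thousand
steps.
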