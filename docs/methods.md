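# Methods

`anastoflow` models the pulsatile hemodynamics of a coronary end-to-side
anastomosis whose orifice has been narrowed by restrictive suturing
("purse-stringing"), together with graded stenosis of the native coronary
artery upstream of the graft. The quantities of interest are the near-wall
metrics that correlate with intimal hyperplasia and graft failure:
time-averaged wall shear stress (TAWSS), the oscillatory shear index (OSI),
relative residence time (RRT), and the extent of flow separation and
recirculation around the suture line.

## Geometry: a planar analogue of the anastomosis

The physical reference is an end-to-side graft onto the left anterior
descending artery: host artery tapering from 2.8 mm (proximal) to 3.2 mm
(distal) across a 10 mm arteriotomy, with the graft end trimmed to the same
length. The package represents this as an idealized two-dimensional
symmetry-plane geometry: a host channel along x (floor at y = 0, tapered
roof), a graft channel of width 3.0 mm descending onto the orifice at a
30 degree take-off angle, and a funnel connecting the graft tube walls to
the heel and toe corners of the orifice. Both graft parameters are
configurable; neither is uniquely determined by the physical model, so the
defaults are a same-order graft calibre and a take-off angle in the middle
of the range commonly discussed for end-to-side grafts.

The dimensional reduction to 2D is the central design decision. A
three-dimensional, multi-million-element simulation is not a desk-scale
artifact; the planar analogue preserves the features that drive the
comparison across stenosis grades - the heel recirculation, floor
impingement, effective inflow angle, and distal-toe separation - at a cost
of minutes per model. What it cannot represent is out-of-plane motion:
helical flow along the lateral host walls, which the 3D flow develops
under bilateral narrowing, has no planar counterpart. Conclusions specific
to helicity are therefore out of reach of this package (see Limitations).

Stenosis is applied as a fractional reduction of a linear dimension, the
most conservative reading when area- vs diameter-based grading is not
stated:

* **longitudinal shortening** - heel and toe move symmetrically toward the
  orifice centre; orifice length = 10 (1 - grade) mm. Gathering the graft
  end onto a shorter arteriotomy also rotates the graft axis toward the
  perpendicular; the construction encodes this by keeping the graft's
  axial footprint on the host proportional to the orifice length,
  tan(theta_eff) = tan(theta_0) / (1 - grade), i.e. 30 -> 37.6 -> 49.1 ->
  66.6 degrees across the grades. (A funnel with a fixed tube angle was
  tried first and measurably fails to steepen the inflow: its near wall
  flattens exactly as its far wall steepens.) The funnel walls then
  re-attach the displaced heel and toe to the rotated tube.
* **bilateral narrowing** - cosine-profiled constriction bumps on both
  graft walls at the junction reduce the open passage to (1 - grade) of
  the graft width. Cosine smoothing avoids spurious corner singularities.
* **native stenosis** - a 2 mm long cosine-tapered symmetric narrowing of
  the proximal host channel to (1 - native_grade) of its diameter, centred
  7.5 mm proximal of the heel. Total occlusion (100%) is built as a sealed
  wall truncating the proximal segment rather than a near-zero gap, which
  would rasterize into degenerate cells.

Geometries are rasterized onto a uniform Cartesian grid (cell centres
strictly inside the fluid polygon are fluid). Host walls are axis-aligned
by construction so that the wall-shear extraction operates on clean
grid-aligned walls in the regions that matter; the oblique graft walls are
stair-stepped and their shear values are correspondingly noisier.

**Resolution policy.** The solver needs several cells across a passage to
resolve it. The generator warns when the narrowest *anastomotic* passage
falls below 8 cells and refuses below 6. At the default spacing
h = 0.1 mm the severest model (bilateral 75%, 0.75 mm passage) spans 7.5
cells - resolved, with a warning on record. The native-stenosis throat is
deliberately exempt from this rule: at 90% it is a 0.28 mm orifice whose
only role is to throttle proximal inflow, no wall metrics are evaluated
inside it, and resolving it at 8 cells would force h = 0.035 mm and a
roughly 25x cost increase for no benefit to the reported quantities.

## Boundary conditions

The simulation domain starts at the graft and proximal native artery; the
aorta is lumped:

* **Aortic inflow**: raised-cosine systolic ejection over 35% of the 1 s
  cycle, a small end-systolic reverse notch (valve closure), and a low
  diastolic bump. The waveform is rescaled analytically so its discrete
  cycle mean is exactly 5.0 l/min.
* **Aortic pressure**: a two-element Windkessel (compliance 1.5 ml/mmHg)
  driven by that inflow. For this model the periodic mean obeys
  mean(p) = p_distal + R_total mean(Q) exactly under trapezoidal
  integration, so R_total = 96/5.0 = 19.2 mmHg.min/l is a closed-form
  calibration; the resulting waveform swings roughly 79-116 mmHg around a
  96 mmHg mean.
* **Coronary outlet impedance**: a smooth two-level periodic resistance,
  elevated 5x during systole (intramyocardial compression), cosine-blended
  over 50 ms transitions. With the defaults (900/4500 mmHg.min/l) the
  lumped circuit places ~86% of coronary flow in diastole - the
  diastolic-dominance criterion that calibrates the impedance shape.
* **Upstream resistances**: the aortic pressure node feeds the graft inlet
  through 300 mmHg.min/l and the native inlet through 2000 mmHg.min/l.
  The graft value is stored in the config and was chosen once so the
  reference-model mean graft flow lands near the 60 ml/min target typical
  of a left-sided arterial graft (the simulated value is within a few
  percent; `calibrate_graft_resistance` re-derives it by bisection against
  any target). The native value represents the diseased epicardial segment
  upstream of the modelled 2 mm lesion; with the geometric throat in
  series it yields a proximal trickle of roughly 8 ml/min, an order of
  magnitude below graft flow, as expected distal to a 90% lesion.

Each open boundary is closed by a lumped pressure node: source pressure,
series resistance (time-varying at the outlet), and a small node
compliance C = 2e-12 m^3/Pa. The compliance is the numerical relaxation
that keeps the boundary coupling stable for arbitrarily large resistances;
its RC time constants (2-70 ms) are small against the cycle and smooth
rather than distort the waveforms. Fluxes between the domain and the
nodes are measured after each projection step, and the node update is
semi-implicit in the resistive term.

Units: configs and reports are clinical (mm, l/min, ml/min, mmHg); the
solver is SI throughout, with conversions centralized in one module.

## Flow solver

Incompressible Newtonian blood (rho = 1060 kg/m^3, mu = 0.004 Pa.s) in a
rigid-walled domain, solved by a fractional-step projection method on a
staggered MAC grid with stair-step masked walls:

* advection: 2nd-order upwind with van Leer limiting (1st-order fallback
  where the second upwind neighbour is a wall or boundary; configurable to
  fully 1st-order);
* diffusion: explicit central differences with reflective tangential
  ghosts (the viscous dt limit, 0.2 h^2/nu, is not binding at these
  parameters - the advective CFL is);
* pressure: a Poisson solve with Neumann walls and Dirichlet open
  boundaries, discretized identically to the divergence/gradient pair so
  the projected field is divergence-free to the precision of the linear
  solve. The matrix is constant, factorized once per geometry (sparse LU,
  MMD ordering) and reused every step; recorded frames show divergence at
  the 1e-10 1/s level.

Time steps obey dt = min(0.4 h/u_max, 0.2 h^2/nu, 50 us); the step count
per cycle is fixed in advance from the previous cycle's maximum velocity
(1.3x margin), and a CFL breach aborts the cycle, which is then retried
from its starting state with twice the steps. The 50 us cap also bounds
the boundary-node coupling gain.

With the default conditions the flow is laminar (cycle Reynolds numbers of
order 10^2-10^3 at the stenotic jets); the solver logs Re per cycle and
warns above 2000.

**Periodicity.** Cycles repeat from rest until the end-of-cycle velocity
field changes by less than the periodicity tolerance (relative L2,
default 1e-3), up to a cycle cap; an infinite tolerance reproduces the
single-cycle protocol. In practice the anastomosis flow does not settle to
a strictly periodic state: the confined 2D jet sheds vortices, and the
cycle-to-cycle residual plateaus near 0.3 rather than decaying (1.00,
0.61, 0.75, 0.31, 0.28 over five cycles on the reference model). This
unsteadiness is physical for a planar jet at these Reynolds numbers. All
analyses therefore use the final recorded cycle; the comparison runs use
one warm-up cycle plus one analysis cycle (the study driver defaults to
three cycles), which is enough for the region-level metrics to stabilize -
the reference model's region extrema move by only a few percent between
cycles 2, 3 and 5 - while keeping each model a few minutes on one core.
The residual is reported with every run.

## Near-wall hemodynamics

Wall shear stress is sampled along each wall polyline at the grid spacing:
the tangential velocity is probed at distances h and 2h along the inward
normal and differenced through the no-slip wall with a two-point quadratic
fit, tau = mu (4 u1 - u2)/(2 d); the sign follows the wall's arclength
tangent. Samples whose probes leave the fluid (sharp corners) are excluded.
On the Poiseuille oracle at 40 cells across, this extraction is accurate
to 0.2%.

Because the flow is planar the shear is a signed scalar, and OSI takes its
scalar form OSI = (1 - |mean tau| / mean |tau|)/2 - equivalent to the
usual vector definition restricted to the plane; 0 where the shear never
reverses, 0.5 for zero-mean oscillation, defined as 0 where the shear
vanishes identically. Quadrature over the recorded phase frames uses the
periodic rectangle rule (= trapezoid under periodic closure), which agrees
with a 10^6-point midpoint oracle to better than 1e-6 on smooth series.
RRT = [(1 - 2 OSI) TAWSS]^-1 is capped at 1/eps (eps = 1e-6 Pa) with an
explicit flag column instead of emitting infinities.

A wall point is "reversed" at a phase when its shear opposes the bulk flow
direction of its wall (taken from the sign of the cycle-mean flux at the
adjacent boundary). Contiguous runs with reversed fraction > 0.5 spanning
more than 3 samples are reported as separation/recirculation zones - the
threshold selects persistent reversal rather than transient phase reversal.
The heel vortex is additionally quantified by the circulation of the
cycle-mean field over the heel pocket.

**Regions A-G.** The seven analysis regions have no unique quantitative
definition, so the package anchors them to the heel and toe landmarks,
which makes the windows track morphed geometries: A = heel +-1 mm (proximal roof + graft near wall);
B = graft near wall 1-4 mm from the heel; C = toe +-1 mm; D = distal roof
1-5 mm beyond the toe; E = the floor opposite D; F = floor within 1.5 mm
of the heel; G = floor 1.5-6 mm proximal of the heel. Interval edges are
half-open so adjacent regions never overlap; all widths are configurable.

The jet angle reported per model is the direction of the momentum
carried across the orifice section by the cycle-averaged velocity field,
measured downward from the host axis. Two estimator choices matter and
both are deliberate: samples are weighted by their downward mass flux
(flow sliding *along* the section carries no weight, which would
otherwise bias the angle toward the horizontal wherever the section is
much longer than the jet), and the field is phase-averaged *before* the
angle is taken (single-frame estimators move by ten degrees or more
between frames of the shedding jet; the mean-field value is
reproducible). Per-frame and peak-flow-frame variants remain available.

## What the synthetic conditions do and do not establish

The generator and boundary conditions emulate the *study conditions*: the
printed fluid properties, flow and pressure set-points, cycle period, the
14-model stenosis matrix, and diastolic-dominant coronary perfusion. They
do not emulate: three-dimensional secondary/helical flow, vessel
compliance and cardiac motion, side branches or collaterals, non-Newtonian
rheology, or patient-specific waveform shapes (the literature waveforms
behind the original boundary conditions are not reproduced in print, so
the package synthesizes standard shapes with the printed means enforced
exactly). Passing tests therefore establish that the *pipeline* computes
its defined quantities correctly and that the planar analogue reproduces
the qualitative ordering of the findings - low-WSS/high-OSI at the distal
toe appearing at 75% stenosis, OSI ~0.5 in the proximal recirculation,
RRT rising under total native occlusion - not that absolute wall-shear
values transfer to any particular 3D anatomy.

## Numerical choices and degenerate inputs

* Poisson: direct sparse LU; no iteration tolerance enters the solution.
  Closed domains (validation boxes) pin the pressure gauge at one cell and
  project the source term onto the compatible space.
* Windkessel ODE: Crank-Nicolson, iterated to a periodic cycle (1e-8
  relative cycle-closure by default), which preserves the discrete
  mean-pressure identity exactly; C = 0 short-circuits to the algebraic
  limit.
* Waveform containers enforce uniform sampling and exact periodic closure
  at construction.
* RRT capping, OSI-at-zero-shear, empty region windows (flagged rows) and
  sealed host inlets (closure simply absent) are all defined cases, not
  errors.
* Determinism: there is no randomness anywhere in the pipeline; identical
  configs produce byte-identical tables.

## Problem sizes

Default study conditions: h = 0.1 mm (about 12,000 fluid cells per model,
28 cells across the proximal host), 20,000-80,000 time steps per 1 s
cycle depending on the peak jet speed, 50 recorded phase frames per cycle,
3 cycles for the models quoted in comparisons. These sizes were chosen as
the package's desk-scale operating point: each model completes in a few
minutes on a single core while keeping the stenotic throat resolved and
the region metrics stable cycle-to-cycle.

## Known limitations

* No helical/out-of-plane flow: bilateral narrowing is represented only
  through its orifice constriction, so lateral-wall helicity findings
  cannot be reproduced or refuted here.
* The distal-toe separation changes character in the plane. A 3D
  separation bubble is weak and near-stagnant because fluid escapes
  laterally; the planar bubble cannot spill sideways, so at 75% stenosis
  (either pattern) the detached shear layer flaps energetically - OSI
  reaches 0.49-0.50 in the distal-toe region, but at shear amplitudes of
  a few tenths of a Pa up to ~1 Pa rather than the near-zero magnitudes a
  stagnant 3D bubble carries (the region-D TAWSS minimum stays around
  0.3 Pa). The planar analogue therefore reproduces *where* the
  disturbed-flow region forms, its oscillatory character and how it
  scales with grade, but not the combination of full oscillation with
  near-zero shear magnitude.
* Stair-step walls give first-order shear accuracy on the oblique graft
  walls; region B values are noisier than host-wall regions.
* The native-stenosis throat is under-resolved by design (see Resolution
  policy); its internal shear field is not meaningful and is never
  reported.
* The confined planar jet is unsteady, so strict cycle periodicity is
  unattainable; reported metrics carry the cycle-to-cycle variability
  documented above.
* Lumped boundary nodes add small RC smoothing (up to ~70 ms at the
  outlet during systole), slightly softening the systolic impedance
  transition.
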