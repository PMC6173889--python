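# Methods

`etflow` models the fluid mechanics of catheter embryo transfer (ET): a
transferred medium carrying embryos is injected through a transcervical
catheter into a uterine cavity filled with much more viscous uterine fluid,
and the catheter is then withdrawn. The package answers two questions about
that procedure: where does the medium disperse (and with it, the embryos),
and how hard must the plunger push.

## Model

**Geometry.** The computational domain is the half mid-sagittal cross
section of an average uterine cavity: a triangular cavity (base 32 mm at
the fundus, height 50 mm) joined to a straight cervical channel (length
25 mm, full width 4 mm), with symmetry about the midline. A catheter
(0.6 mm / 0.8 mm inner/outer diameter, 56 mm inside the domain) lies along
the midline with its tip 15 mm from the fundus. Two 0.3 mm openings
represent the fallopian-tube ostia (one in the half domain, at the lateral
corner of the fundus); the 4 mm external ostium terminates the cervix.
Because the triangle's apex would pinch the cervix–cavity junction to zero
width and seal the cavity, the channel walls are extended to where the
sloped cavity wall reaches the channel half-width (x = 31.25 mm); the
junction shape is not dimensioned in the source geometry and this is the
simplest open configuration.

**Mixture flow.** Both fluids are incompressible and miscible and share one
local velocity (homogeneous multiphase/mixture model). Composition is
tracked by the transferred-medium volume fraction α with

    rho_m = α rho1 + (1-α) rho2,      mu_m = α mu1 + (1-α) mu2,

mass and momentum conservation for (u_m, p), and a pure advection equation
for α (inter-phase diffusion is neglected: the flow is convection
dominated over the 1–15 s injection). Since both phases are incompressible,
the mixture velocity is divergence free. The uterine fluid is
glycerin-like: rho2 = 1259.9 kg/m³, mu2 = 0.799 Pa·s. The medium viscosity
spans 0.001 Pa·s (saline) to 0.799 Pa·s (equal-viscosity) over nine
tabulated cases; all inject 20 µL, over 1 s (fast) or 15 s (slow). The
corresponding plug inlet speeds through the circular bore area πr_c² are
70.7 and 4.72 mm/s; peak Reynolds number ≈ 42 — laminar.

**Boundary conditions.** No-slip/no-penetration on all walls; during
withdrawal the tip, inner and outer catheter walls move at the withdrawal
speed (moving-wall condition); gauge pressure 0 with zero-gradient
velocity/α at both ostia; plug inflow with α = 1 at the bore entrance
during injection, a closed (and, during withdrawal, moving) plunger after.
The inlet profile shape is not constrained by the problem statement; plug
flow is used and develops inside the 56 mm bore (entrance length ≪ bore
length at Re ≈ 42).

**Embryos.** Ten rigid spheres (d_e = 0.1 mm, rho_e = 1000 kg/m³) start at
rest 10 mm behind the tip, at the radial midpoints of ten equal-area zones
of the bore cross-section, r_i = √(i/10) (r_c − r_e): a deterministic
stand-in for the uniform radial loading probability. Each embryo obeys
drag-only dynamics dv_e/dt = β (u_m − v_e) with the Morsi–Alexander
piecewise drag coefficient and slip Reynolds number
Re_r = 2 rho_m r_e |v_e − u_m| / mu_m; embryos do not affect the flow and
do not interact, so the ten trajectories are independent simulations.

Two drag prefactors are selectable. The `standard` form,
β = 3 mu_m C_D Re_r / (16 rho_e r_e²), has the conventional Stokes limit
9 mu / (2 rho_e r_e²); the `paper` form is exactly twice that. For these
parameters β·Δt ≫ 10 in every case, so the embryo velocity relaxes to the
local fluid velocity within a single step either way and delivery sites are
insensitive to the choice (asserted in the suite); `standard` is the
default.

## Numerics

Finite volumes on a tensor-product Cartesian grid with solid-cell blanking:
the sloped wall is stair-stepped and the catheter is a time-dependent solid
mask, which turns withdrawal into mask motion instead of mesh motion.
Moving-solid faces prescribe the wall-normal volume flux u_wall·n A (piston
fluxes), which reproduces both the push at the advancing plunger and the
suction behind the receding tip; cells uncovered by the mask are seeded
from their fluid neighbours.

- Colocated variables with Rhie–Chow momentum interpolation; SIMPLE
  pressure–velocity coupling with under-relaxation 0.7 (momentum) / 0.3
  (pressure). The pressure-correction equation is solved directly (sparse
  LU), so the stored face fluxes are divergence free to round-off after
  every outer iteration; the outer loop stops when the pre-correction flux
  imbalance falls below 1e-4 of the boundary inflow (default), which bounds
  the remaining momentum–pressure lag, not mass conservation.
- First-order upwind convection and first-order implicit time stepping
  (unconditionally stable), matching the original study's scheme orders.
- α transport: implicit upwind with the divergence-free face fluxes; the
  scheme is monotone, so α stays in [0, 1] up to round-off (clipped and
  logged beyond 1e-10). The discrete α budget closes to machine precision
  against the boundary fluxes.
- The transposed-gradient part of the stress, which for divergence-free
  fields reduces to (∇mu)·(∇u)ᵀ concentrated at the medium–fluid interface,
  is available as an explicit source (`transposed_stress=True`) but is off
  by default: at desk-scale time steps its explicit treatment is unstable
  (effective interface CFL ≫ 1), and it vanishes identically wherever the
  viscosity is uniform.
- Embryo integration: the drag ODE is stiff (relaxation times of
  microseconds), so the velocity is updated with the exact exponential
  solution over each step holding the sampled fluid velocity frozen, and
  the displacement follows by the trapezoidal rule. Local flow is sampled
  by bilinear interpolation from cell centres; blanked cells carry the wall
  velocity. An embryo stepping into a blanked cell is pushed back to the
  nearest fluid cell centre (counted; zero in converged runs).

**Resolution and time step (desk-scale presets).** The printed scheme uses
Δt = 1e-4 s; the implicit solver is stable at much larger steps, and the
built-in cases use Δt = 1 ms during fast injection (5 ms for slow
injection) and 2.5 ms during withdrawal, with snapshots every 100 steps.
The default mesh uses 0.1 mm cells across the bore and catheter wall near
the midline (three cells across the half bore), 0.5 mm axially near the
tip, and grades to 1 mm (axial) / 2.5 mm (lateral) elsewhere —
approximately 1,300 fluid cells. These presets were fixed from
stability/accuracy reasoning at desk scale; a refinement check (0.75 mm
coarse spacing, 0.4 mm at the tip, Δt_w = 2 ms) moves the case-1 drag-back
by +1%, the case-7 drag-back by +16% and the force ratio by +12%, i.e. the
reference-case withdrawal metrics are grid-robust while the equal-viscosity
drag-back is the most resolution-sensitive quantity.

## Post-processing

- **Dispersion pattern**: marching-squares contour of α = 0.5 (blanked
  cells NaN-masked), mapped to physical coordinates. Pattern area uses
  closed loops where they exist, else the area of cells with α ≥ 0.5.
  Shape classification is a documented heuristic: medium area behind the
  tip plane outside the catheter (> 1 mm² ⇒ `incomplete_ellipse`, else
  `sector`).
- **Transport distances**: per-embryo axial (x − 60 mm, + toward the
  fundus) and radial (|y|) distances at the end of injection; downstream
  means strictly fundus-side of the tip plane (the plane itself counts as
  upstream — tie-break convention).
- **Drag-back**: mean of x(end of injection) − x(end of withdrawal) over
  the ten embryos; the summary also counts embryos ending cervix-side of
  the internal os and embryos leaving the domain.
- **Driving force**: mean gauge pressure over the inlet cells × πr_c²
  (circular-bore area convention, the only one consistent with the
  tabulated magnitudes for this planar model; the per-unit-depth 2D force
  is also available). The time-mean over the injection is used for
  case-to-case comparisons; the full time series is stored.

## What the model does and does not capture

The solver reproduces the qualitative regime change the study reports: a
saline medium jets into the viscous ambient and recirculates back along
the catheter (incomplete-ellipse pattern with upstream lobes, about half
the embryos delivered upstream), while an equal-viscosity medium spreads as
a sector with all embryos delivered downstream, at a driving force two
orders of magnitude higher. Quantities that depend on resolving thin
boundary layers are only approximate at desk scale: first-order upwinding
adds numerical viscosity of order rho·u·h/2 ≈ 0.02 Pa·s in the jet, which
smears the saline jet's vortex, and the lubrication-scale layer on the
moving catheter wall is unresolved — so no simulated embryo remains
attached to the withdrawing catheter long enough to be dragged into the
cervix, although the mean drag-back distances agree with the tabulated
values. The model is 2D planar: out-of-plane spreading, uterine
peristalsis, embryo buoyancy/lift and embryo back-reaction on the flow are
out of scope.

## Determinism

There is no randomness anywhere: the ten start positions are fixed
midpoints of the equal-probability zones, and reruns of a configuration
produce bit-identical trajectories and summaries.
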