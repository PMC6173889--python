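# etflow

A 2D computational model of **embryo transfer (ET)** — the final step of
IVF, in which embryos suspended in a transfer medium are injected into the
uterine cavity through a transcervical catheter, which is then withdrawn.
`etflow` simulates the intrauterine mixing flow of the injected medium with
the viscous uterine fluid and tracks the embryos through it, for people
studying how the medium's viscosity and the injection speed shape where the
embryos are delivered and how roughly they are handled.

## Model in brief

The transferred medium (phase 1) and uterine fluid (phase 2) form an
incompressible laminar **homogeneous mixture**: one velocity field u_m, one
pressure p, and a transferred-medium volume fraction α with

    ∂ρ_m/∂t + ∇·(ρ_m u_m) = 0
    ∂(ρ_m u_m)/∂t + ∇·(ρ_m u_m u_m) = −∇p + ∇·(μ_m(∇u_m + ∇u_mᵀ))
    ∂(αρ₁)/∂t + ∇·(αρ₁ u_m) = 0
    ρ_m = αρ₁ + (1−α)ρ₂,   μ_m = αμ₁ + (1−α)μ₂

solved by a finite-volume SIMPLE scheme (first-order upwind / implicit) on
a half uterine-cavity geometry with a blanked, movable catheter. Ten
embryos (spheres, d_e = 0.1 mm, ρ_e = 1000 kg/m³) are tracked one-way with
drag-only dynamics

    dv_e/dt = β(Re_r) (u_m − v_e),   Re_r = 2ρ_m r_e |v_e − u_m| / μ_m

using the Morsi–Alexander drag correlation, starting from the midpoints of
ten equal-area zones of the bore cross-section (r_i = √(i/10)(r_c − r_e)).
Nine built-in cases sweep μ₁ from 0.001 Pa·s (saline) to 0.799 Pa·s (equal
to the uterine fluid) at fast (1 s) and slow (15 s) injection of 20 µL;
5 s of catheter withdrawal follows for the reference (1) and
equal-viscosity (7) cases. See `docs/methods.md` for assumptions,
numerics and limitations.

## Worked example

```sh
$ etflow run --case 7 --outdir run7
case 7: mean axial 6.77 mm, mean radial 3.14 mm, driving force 28.423 mN, dragback 3.60 mm (0 exited the cervix)
```

Reading: at the end of the 1 s injection the ten embryos sit on average
6.77 mm fundus-side of the catheter tip (all ten in the downstream region —
the clinically favourable side) and 3.14 mm off the midline; pushing the
equal-viscosity medium takes a time-mean driving force of about 28 mN on
the bore cross-section; the 5 s withdrawal drags the embryos back 3.60 mm
on average, and none is pulled into the cervix. The same command with
`--case 1` (saline) gives a mean axial distance of ~0.4 mm with half the
embryos upstream, a force of ~0.2 mN, and a mean drag-back of ~7.9 mm:
low-viscosity media leave embryos nearer the cervix and far more exposed to
the withdrawal, which is the model's central comparison.

The run directory contains the config copy, trajectory / force / budget
CSV tables, the α = 0.5 dispersion-contour polyline and a VTK snapshot
series. `etflow list-cases` prints the nine case parameterisations;
`etflow summarize run7` recomputes the delivery table from the stored CSVs.

From Python:

```python
from etflow import builtin_case, run_case
result = run_case(builtin_case(1))
print(result.summary.mean_axial_mm, result.pattern.shape_class)
```

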