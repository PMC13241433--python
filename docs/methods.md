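# Methods

## Physical model and assumptions

The arterial segment is a straight, axisymmetric, thick-walled cylinder in
plane strain (axial stretch fixed at 1, no torsion), loaded by a steady
transmural pressure difference Δp between the lumen and the outer bath.
The wall is a fully saturated biphasic mixture: a porous, anisotropic
hyperelastic solid skeleton and interstitial fluid, both intrinsically
incompressible. The outer-bath fluid pressure is the zero reference, so
the pore pressure runs from p(a) = Δp to p(b) = 0 and drives a steady
radially outward filtration, described as a line source with flow rate Q
per unit axial length (φ_f v_f = Q/2πr). The *effective* (Terzaghi)
traction is zero at both surfaces: the skeleton is mechanically
unconstrained there, and the entire transmural load is carried into the
wall by the pore fluid (seepage forces). Consequently the total radial
stress at the lumen equals −Δp, while the skeleton's own radial stress
vanishes at both surfaces.

Macroscopic volume change is a porosity change: J_e = λ_e,r λ_e,θ =
(1 − φ_f,0)/(1 − φ_f). This is what lets the model reproduce large
apparent compressibility (tens of percent at low pressure) while both
constituents stay incompressible — the central point of the framework.

Residual stress is represented by a prescribed pre-stretch F_p in the
zero-pressure reference configuration (multiplicative split F = F_e F_p).
The circumferential profile is linear in the reference radius,

    λ_p,θ(R) = 1 + g (R − R_mid)/(b₀ − a₀),

so the mid-wall value is exactly 1 and g is the total change across the
wall. The gradient convention is **per wall thickness** (dimensionless),
an assumption the underlying formulation leaves open; g ∈ [0, 0.15] is the
scanned range. Pre-stretch is evaluated at the reference coordinate
R(r) = r − u_s(r), since F_p is defined in the reference configuration.
Two radial couplings are implemented: case 1, λ_p,r = 1 (weak transverse
coupling) and case 2, λ_p,r = 1/λ_p,θ (volume-preserving, det F_p = 1).
The constitutive law is applied to the *total* stretches also when
pre-stretch is present (elastic-only energy would be the alternative; the
literal composition is implemented).

## Constitutive choices

Strain energy W = W_dev + W_vol:

- W_dev = (C/2)(exp(Q̃) − 1), with Q̃ the quadratic form
  b₁Ẽ_θ² + b₂Ẽ_z² + b₃Ẽ_r² + 2b₄Ẽ_θẼ_z + 2b₅Ẽ_rẼ_z + 2b₆Ẽ_θẼ_r in
  deviatoric Green–Lagrange strains Ẽ_m = (λ̃_m² − 1)/2, λ̃_m = J^(−1/3)λ_m.
  Note λ̃_z = J^(−1/3) ≠ 1 whenever J ≠ 1, so the axial terms (b₂, b₄, b₅)
  remain active under plane strain.
- W_vol = K_v(exp(f(J)) − 1) with f(J) = β(J−1)^γ + (J−1)²/2 for J ≥ 1 and
  (K_v/2)((J²−1)/2 − ln J) for J < 1. Both branches and their first
  derivatives vanish at J = 1 (C¹); the compression branch is a standard
  log barrier that prevents nonphysical collapse.

Effective stresses σ′_m = (λ_m/J)∂W/∂λ_m are **hand-derived in closed
form**, with λ_z = 1 held fixed and the J-dependence (isochoric factors and
W_vol) differentiated through:

    σ′_m = (C/J) e^Q̃ (S_m λ̃_m² − ⅓ Σ_n S_n λ̃_n²) + dW_vol/dJ,

where S_m = ½ ∂Q̃/∂Ẽ_m. The deviatoric part is exactly trace-free over
(r, θ, z); the volumetric part is hydrostatic. Finite differences are
never used in production — they serve only as the independent oracle in the
test-suite (agreement to 1e-5 relative over λ ∈ [0.7, 1.8]²). σ′_z is a
plane-strain reaction not needed by the 1-D balance and is not exposed.

Permeability follows Kozeny–Carman,
k = k₀ · (1−φ_f,0)²/φ_f,0³ · φ_f³/(1−φ_f)², normalized so k(φ_f,0) = k₀
and strictly increasing in φ_f. A useful structural fact: in the steady
problem a constant rescaling of k rescales Q but leaves the deformation and
stresses unchanged (the seepage force field Q/(2πk) is invariant), so k₀
sets transport magnitudes only.

Exponents fed to exp() are capped at 700; an overflowing state produces a
non-finite energy/stress that the Newton line search treats as a rejected
step. This keeps the extreme corners of the identification grid from
crashing the sweep.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| a₀, b₀ | reference inner/outer radius | mm | 0.31, 0.42 |
| φ_f,0 | reference porosity | – | 0.40 |
| k₀ | reference permeability | mm⁴/(N·s) | 2.8×10⁻³ |
| C | Fung modulus | kPa | 210 (best fit) |
| b₁…b₆ | Fung exponents (θ, z, r and couplings) | – | 0.9925, 0.4180, 0.0089, 0.0749, 0.0295, 0.0193 |
| K_v | volumetric modulus | kPa | 9.0 (best fit) |
| β, γ | expansion shape/exponent | – | 1.5, 4.8 (best fit) |
| N | element count | – | 100 |
| g | pre-stretch gradient per thickness | – | 0 (scan 0–0.15) |

Internally everything runs in the mm–N–s system (stresses in MPa), which
closes dimensionally with k₀ as tabulated; configs accept mmHg for
pressures (1 mmHg = 1.33322×10⁻⁴ MPa) and kPa for moduli, and profile
outputs report stresses in kPa.

## Discretization and solver numerics

Unknown vector x = (u_s at the N+1 nodes, Q, a, b). Nodes sit at fixed
normalized coordinates ξ ∈ [0, 1] with r = a + (b − a)ξ, so (a, b) are
explicit unknowns and the weak-form integrals differentiate through the
moving domain. The N+1 Galerkin equations use hat test functions including
both boundary nodes (the zero effective traction is natural, so there is no
essential condition on u_s); Q keeps the pressure-drop constraint as its
own equation, and two geometric constraints close the system at N+4. All
integrals — including 1/(kr) — use 2-point Gauss quadrature per element.

The Newton Jacobian is evaluated by **complex-step differentiation**
(step 10⁻³⁰) of the residual, which is analytic in the unknowns; this is
exact to machine precision and equivalent to forward-mode automatic
differentiation, with none of the subtractive cancellation of finite
differences. A backtracking line search (halving, up to 40 times) rejects
steps whose residual is non-finite — which is how inadmissible states
(collapsed kinematic denominators, porosity outside (0, 1), inverted mesh)
are handled. Convergence: ‖res‖ < max(10⁻¹², 10⁻¹⁰‖res₀‖), cap 50
iterations. Pressure is applied by warm-started continuation in 5 mmHg
steps, halved on failure down to 0.15625 mmHg; the zero-pressure state is
re-equilibrated first (with pre-stretch it is not exactly stress-free; the
resulting (a, b) shift from (a₀, b₀) at Δp = 0 is small but nonzero).

Nodal output profiles evaluate the kinematics with averaged
adjacent-element displacement gradients (one-sided at the surfaces, O(h)
there). Because of that, the *pointwise* constitutive σ′_r at a boundary
node is only O(h) close to zero; the discretely meaningful boundary
traction is recovered consistently from the boundary-node weak-form
equation (reaction recovery) and vanishes to solver tolerance. Pore
pressure is recovered by the same quadrature as the pressure-drop
constraint, so p(b) = 0 by construction and p(a) reproduces Δp to solver
tolerance. Apparent measures converge at second order in 1/N (measured
ratio ≈ 4.0 when doubling N).

Verification: the Galerkin solution is checked against an independently
formulated strong-form oracle — a Lagrangian shooting solver that
integrates the momentum balance as an ODE in the reference coordinate,
inverts σ′_r pointwise for λ_r, and shoots on (a, Q) — agreeing to better
than 10⁻⁶ relative in (a, b, Q) and the displacement profile.

## Identification and pre-stretch analysis

Apparent measures referenced to the 15 mmHg state: Λ_r = (b−a)/(b̄−ā),
Λ_θ = (b+a)/(b̄+ā), 𝒥 = (b²−a²)/(b̄²−ā²) (identically Λ_rΛ_θ). The error
metric is the mean L1 relative deviation at 40, 80, 120, 160 mmHg per
measure, in percent; E_tot is their sum. The sweep enumerates the Cartesian
grid C ∈ [20, 300] kPa (step 10), K_v ∈ [5, 50] kPa (step 1),
β ∈ [0.1, 3.0] (step 0.1), γ ∈ [2, 10] (step 0.2) — 1,640,820 cases at
full resolution; a per-axis stride supports desk-scale runs. Ranking is
deterministic with lexicographic tie-breaks on (C, K_v, β, γ); the
lowest-error subset takes floor(1% of converged cases), minimum 1.
Non-converged cases are recorded and excluded from ranking.

The homogenization scan evaluates E_var = |σ′_θ,max − σ′_θ,min| across the
wall at a fixed **evaluation pressure of 100 mmHg** — a mid-physiological
choice the analysis leaves open; it is exposed as an argument. The scan
walks g in steps of 10⁻³ (the CLI default; consecutive solves warm-start
each other so each g costs one Newton solve), selects the interior local
minimum with the smallest E_var, and refines it by bounded scalar
minimization between the neighbouring grid points. At the selected g the
circumferential stress spread collapses by more than an order of magnitude
relative to g = 0, i.e. σ′_θ is nearly uniform across the wall.

## Synthetic pseudo-experiments

Real inflation-rig records (apparent stretches averaged over wall regions
and specimens) exist only as published plots, so the identification
pipeline is exercised against generated data: the forward model is run at
known parameters and each measure is multiplied by (1 + ε),
ε ~ N(0, cv) with seeded pseudo-randomness (default cv = 1%, the scale of
relative scatter such measurements show; multiplicative because the
measures are ratios near 1–1.6). The generator reproduces the *statistical
structure* of such data — smooth pressure–stretch curves with relative
noise — but not specimen-to-specimen biological variability, local
measurement optics, or systematic bias; passing recovery tests therefore
demonstrate identifiability of the model given its own dynamics, not
field accuracy on real tissue. With cv = 0, grid-search recovery of
on-grid generating parameters is exact and the generating error is
identically zero, which is used as an oracle.

## Problem sizes used in the test-suite

Solver unit tests run at N = 25–50; the oracle comparison at N = 200;
mesh-convergence checks at N = 25–200; end-to-end behavioural checks at
the production N = 100; recovery experiments use a well-separated 2⁴
parameter grid at N = 25 with pressure levels {15, 40, 80, 120, 160} mmHg.
These sizes make the full suite a few minutes on one CPU while keeping
every check at, or above, the resolution where the measured quantities are
mesh-converged to well below the asserted tolerances.

## Known limitations and numerical sensitivities

- Steady state only: no transient poroelasticity, inertia, or pulsatile
  loading; no axial force balance; single-layer wall; no fiber-based 3-D
  anisotropy.
- The low-pressure radial effective stress is a near-cancellation: the
  Laplace-type rise (σ′_θ/r) and the seepage pull (Q/2πkr) integrate to the
  same total, and their pointwise difference at 15–40 mmHg is ~1% of σ′_θ
  (sub-0.25 kPa). The *sign* of the small peak σ′_r in that regime is
  therefore at the edge of the model's structural resolution: the computed
  peak is slightly tensile already at 15 mmHg without pre-stretch, while
  with the homogenizing pre-stretch the same balance produces clearly
  compressive low-pressure states and tensile transitions at 80 mmHg
  (case 1) and between 80 and 100 mmHg (case 2). Conclusions that hinge on
  the exact zero-crossing pressure of the no-pre-stretch peak should be
  drawn with this sensitivity in mind.
- The identification is a representative fit, not a unique one: broad
  parameter combinations produce similar apparent-deformation errors, so
  best-fit values should be read jointly with the lowest-error subset.
- Grid-search cost scales with the full Cartesian product; the full
  1.6-million-case sweep is intended for cluster-scale runs (it is
  embarrassingly parallel and order-independent), while strided grids
  reproduce the mechanics at desk scale.
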