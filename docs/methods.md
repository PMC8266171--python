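# Methods

This note records the model equations as implemented, the numerical choices,
the parameter defaults with units, what the shipped synthetic scenarios do
and do not emulate, and known limitations.

## Continuum model

**Mechanics.** Quasi-static equilibrium `∇·σ = 0` (growth is slow; inertial
and non-compliant terms neglected). The deformation gradient follows from
the displacement as `F = (I − grad u)⁻¹` in spatial form; the assembly works
in the equivalent total-Lagrangian form `F = I + Grad u` on the reference
configuration. Growth splits multiplicatively, `F = F_e F_g` with
`F_g = (1+α) I`; in 2D (plane strain, a cross-section of a long vessel)
growth acts in-plane only, with unit out-of-plane stretch, since axial
overgrowth of a cross-section model is unobservable. The Cauchy stress is
`σ = J_e⁻¹ (∂Ψ/∂F_e) F_eᵀ` from the HGO-type free energy

```
Ψ = μ/2 (I1m − 3)
  + (η/β) exp(β [ρ ⟨Ī₄−1⟩² + (1−ρ)(Ī₁−3)²])
  + κ_vol (J_e − 1)² − μ log J_e
```

with the isochoric invariants `Ī₁ = J⁻²ᐟ³ tr(F_eᵀF_e)`,
`Ī₄ = J⁻²ᐟ³ n·F_eᵀF_e·n` and the fiber helix direction
`n(θ_az) = [−cosθ_el sinθ_az, cosθ_el cosθ_az, sinθ_el]` evaluated from the
reference azimuth of each Gauss point.

Two conventions are deliberately fixed (both literal alternatives remain
selectable through `MaterialParams` flags):

* **Volumetric coefficient.** `κ_vol = μν/(1−2ν)` (kPa), the standard
  compressible neo-Hookean Lamé combination. The variant `ν/(μ(1−2ν))`
  carries units of 1/kPa and cannot be added to the other energy terms;
  it is available as `literal_volumetric=True`.
* **Matrix-term invariant.** The `μ/2(I1m−3)` matrix term uses the **full**
  first invariant (`I1m = tr F_eᵀF_e`) so that its gradient `μF` cancels the
  `−μF⁻ᵀ` of the log term at identity and an unloaded artery is exactly
  stress free — a property the test suite enforces to 10⁻¹⁰ kPa. With the
  all-isochoric variant (`isochoric_matrix_term=True`) a spurious pressure
  `−μ` remains at the reference state.

The fiber-energy exponent is clipped at 50 (configurable) to avoid overflow
under extreme fiber extension; clip events raise a warning. Fibers resist
tension only: the Macaulay bracket removes `⟨Ī₄−1⟩` in compression, and the
small-strain response is then independent of the dispersion weight ρ.

**Growth law.** `α̇/(1+α) = k_g H(α−α_cri) φ`, where `H(x−x_cri)` is the
threshold gate that is **1 for x ≤ x_cri** — an inverted convention shared
with the nutrient gate: growth proceeds while α is at or below its cap and
stops once it exceeds α_cri. The gate is evaluated at the previous step
(lagged), so each update integrates exactly:
`α_{n+1} = (1+α_n)·exp(k_g φ Δt) − 1` while active, with φ clamped to
[0, 1]. Consequently α can overshoot the cap by at most one increment
`(1+α_cri)(e^{k_g Δt} − 1)`. α lives at the Gauss points and advances once
per converged time step (staggered), never inside Newton.

**Nutrient.** `∇·(D(φ)∇c) − R_c = 0`, steady (diffusion is fast relative to
inflammation), with `D = φ D_min + (1−φ) D_max` evaluated at φ clamped to
[0, 1] and a uniform consumption sink R_c. Boundary data: `c = c_max` on the
lumen surface, natural zero flux on the outer surface, plus `c = c_max` on
all nodes of elements cut by the vasa-vasorum fractals (minus the occluded
tree). With the default c_cri = c_max the scarcity gate of the inflammation
source is open essentially everywhere except at the nourished surfaces;
c_cri is independently configurable. If strong starvation drives c below
zero (a linear equation has no positivity guarantee), c is clamped at zero
only inside the gate evaluations, and a starvation warning is logged.

**Inflammation.** Allen–Cahn dynamics
`φ̇ = −M f′(φ) + ε²∇²φ + S` with `f(φ) = 16 M φ²(1−φ)²`. Note the barrier
parameter appears **twice** — inside f and as the mobility prefactor — so
the effective barrier stiffness scales as M²; the stationary interface is
`φ = (1 − tanh(k x))/2` with slope `k = 2√2 M/ε`, which the test suite
verifies by relaxing profiles at M = 1 and M = 10. The source
`S = R_s H(c−c_cri)(∇φ·∇c)/max(|∇c|, δ_g)` advects the interface with speed
R_s toward decreasing nutrient; δ_g = 10⁻⁸ floors the singular zero-gradient
case. The boundedness penalty `K_p[⟨φ−1⟩² + ⟨−φ⟩²]` holds φ within
[−0.02, 1.02] at K_p = 10⁴ in all shipped runs.

## Discretization and solver

* Structured polar meshes: `n_r = round(t/h)` rings × `n_c ≈ 2πr_mid/h`
  sectors of bilinear quads, extruded into trilinear hexes for tubes.
  Meshes with fewer than 3 rings through the wall are rejected.
* 2×2(×2) Gauss quadrature throughout; 4 (2D) or 5 (3D) DOFs per node in
  node-major `[u | c | φ]` order.
* Backward Euler in pseudo-time; the step is capped so the advective
  Courant number `R_s Δt/h ≤ 1/2`. Δt and t_end are model inputs
  (pseudo-time is nondimensional); defaults Δt = 0.05, t_end = 20.
* Monolithic Newton on `[u, c, φ]` with exact linearization of all terms
  except the lagged quantities — α, the advection direction `∇c/|∇c|` and
  the scarcity/growth gates are frozen at the previous converged step and
  contribute no tangent blocks. The φ-advection and φ-dependent diffusivity
  make the tangent unsymmetric; a direct sparse LU solves the linear
  systems. The mechanical block's fourth-order tangent `dP/dF` is formed by
  central differences of the analytic stress at each Gauss point (step
  10⁻⁶), which preserves near-quadratic convergence at the tolerances used.
* A backtracking line search (accept the longest step that does not grow
  the residual) guards against the non-smooth penalty/Macaulay kinks; on
  Newton failure the time step halves, up to `step_halving_max` times.
* Convergence is an absolute norm on the scaled residual (K_c = K_φ = 1).
  The default 10⁻⁸ is calibrated to ~1 µm² 2D element volumes; the coarse
  3D case uses 2×10⁻⁶, the same relative accuracy for its ~64 µm³ hexes.
* The lumen pressure is a follower load on the deformed inner surface with
  its geometric linearization assembled exactly (in 2D the nodal follower
  force is linear in the deformed coordinates). Pressure ramps linearly
  over `p_ramp_time` (default 1 pseudo-time unit) and is then held.
* Rigid-body modes are removed by minimal point constraints compatible with
  radial breathing (three tangential/axial point conditions in 2D, six in
  3D); the axial ends of the tube remain free to breathe, which avoids
  artificial axial compression and buckling of the growing wall.
* Transport and phase-field integrals are evaluated on the reference
  configuration. This is exact at the (sub-percent) growth magnitudes of
  the default cap; at large pressurized strains it is a small-deformation
  approximation for those two fields.
* Each run starts with a steady nutrient solve at the seeded phase field so
  the first step's lagged advection direction is well defined; the t = 0
  record is the undeformed state, hence stenosis(0) = 0 by construction.

## Vasa vasorum

Tree fractals anchored at equally spaced azimuths on the outer surface
(default 8 per cross-section; staggered axially in 3D), trunk L₀ = 3 µm
pointing inward, then per level k = 2..4 children scaled by λ_k: two
children spread symmetrically by ±γ_k/2 in 2D (γ_k = 2π/3 is read as the
full opening angle), one child per (γ_az, γ_el) pair in 3D (three children
at elevation π/3). Lengths and angles are multiplied by `1 + jitter·N(0,1)`
(default jitter 0.1) from a seeded generator; a fixed seed reproduces the
forest bitwise. Trees are clipped to the outer half of the wall
(mid-wall penetration limit); recursion stops at clipped branch points.
Element tagging is inclusive (boundary touches tag all adjacent elements):
shapely predicates in 2D, half-space clipping against the planar hex faces
in 3D. The initial occlusion removes the entire tree whose anchor azimuth is
nearest the arc coordinate S (measured counter-clockwise along the mid-wall
circle from the +x axis) from the nourishment set, and seeds the phase field
with a smooth tanh-profile disc/ball (radius 2h by default) at mid-wall at
that azimuth.

## Parameters

| group | symbol | default | unit | meaning |
|---|---|---|---|---|
| geometry | D | 50 | µm | lumen diameter |
| | t | 15 | µm | wall thickness |
| | L | 100 | µm | tube length (3D) |
| | S | 30 | µm | occlusion arc coordinate |
| | h | 0.5 | µm | target element edge |
| material | μ | 10 | kPa | shear modulus |
| | ν | 0.49 | – | Poisson ratio (near-incompressible) |
| | η | 100 | kPa | fiber stiffness (0 disables fibers) |
| | β | 1 | – | fiber exponent |
| | ρ | 0.5 | – | fiber/isotropic weighting |
| | θ_el | 60 | deg | fiber helix elevation |
| growth | k_g | 0.25 | 1/time | overgrowth rate |
| | α_cri | 10⁻³ | – | growth cap |
| nutrient | D_max / D_min | 1.0 / 0.1 | µm²/time | healthy / inflamed diffusivity |
| | R_c | 10⁻³ | µg µm⁻³/time | consumption |
| | c_max = c_cri | 1.0 | µg µm⁻³ | blood-contact / scarcity level |
| phase field | ε | 1 | – | interface coefficient |
| | M | 10 | – | barrier |
| | R_s | 0.1 | µm/time | front advection speed |
| | K_p | 10⁴ | – | boundedness penalty |
| solver | p_max | 3.3 | kPa | lumen pressure (25 mmHg) |
| | K_c, K_φ | 1 | – | residual scalings |
| | Δt / t_end | 0.05 / 20 | time | stepping |
| vasa vasorum | L₀; λ₂..₄; γ₂..₄ | 3; 1; 2π/3 | µm; –; rad | trunk; ratios; openings |
| | γ_az; γ_el | 0, 2π/3, 4π/3; π/3 | rad | 3D branching |

## Shipped scenarios and what they show

The canned cases (`atherofem.fixtures.canned_case`) mirror the three
canonical 2D disease configurations — isotropic wall without vasa vasorum,
circumferential in-plane fibers (θ_el = 0), fibers plus an occluded 8-tree
network — and a coarse 3D tube. The shipped *test* resolution is h = 1 µm
(2D) / 4 µm (3D) with Δt = 0.25, t_end = 10 and, importantly, **interface
parameters rescaled to the mesh** (ε = 0.2, M = 0.07 in 2D; ε = 0.4,
M = 0.057 in 3D; seed radius 3–5 µm). The rescaling is forced by the model
structure: with the nominal ε = 1, M = 10 the stationary interface slope is
k = 2√2·M/ε ≈ 28 µm⁻¹ (a ~0.14 µm interface), which no affordable mesh
resolves — an unresolved Allen–Cahn front is lattice-pinned and cannot move
— and the curvature-driven shrink speed ε²/r would exceed the advection
speed R_s for any lesion smaller than ε²/R_s = 10 µm, collapsing the seed.
The test-resolution values keep the diffuse front ~4 elements wide and the
curvature velocity well below R_s, so the *mechanisms* (radial, scarcity-
seeking front advance; VV-steered irregular lesion shapes; growth capped at
α_cri) are preserved at desk scale. The `*_paper` variants retain the
nominal fine-resolution parameter set unchanged for users with the budget
to attempt them.

What passing tests show: the discretization reproduces closed-form
diffusion and elasticity solutions at the expected order, the constitutive
implementation is exact against finite differences and frame-indifferent,
the phase front advects at the prescribed speed, and the coupled driver is
deterministic and conservative under trivial data. What they do not show:
quantitative agreement with any real artery (material values are nominal
literature-scale numbers; the wall is single-layered, residual stresses and
blood flow are absent) nor the magnitude of clinical stenosis — under the
default growth cap α_cri = 10⁻³ the mechanical footprint of the lesion is
sub-percent, and the end-time lumen area is dominated by the elastic
response to the lumen pressure. In particular, a fiber-free wall dilates
far more under pressure than a fiber-reinforced one, so the end-time
stenosis of the three scenarios orders by elastic stiffness, with the
vasa-vasorum case differing only marginally from its fiber-only
counterpart; volumetric growth of a pressurized ring at these magnitudes
dilates the lumen slightly further rather than narrowing it. A
growth-dominated compressive-core / tensile-rim stress signature is
demonstrated separately on an unloaded wall with a raised cap.

## Numerical details and degenerate inputs

* Azimuths are undefined on the axis (error); the branch cut lies on +x.
* Element inversion during a Newton step raises a recoverable failure that
  triggers step halving; persistent divergence aborts with the Newton
  history in the run log.
* Segment/element tagging is endpoint- and boundary-inclusive with a 10⁻⁹
  tolerance; empty trees tag nothing.
* A self-intersecting deformed lumen polygon reports a fully occluded lumen
  (0 µm², 100 % stenosis) with a warning.
* The 1D front-speed fixture freezes the nutrient at a prescribed linear
  profile and clamps mechanics, isolating pure interface advection; speeds
  are fitted on the bottom-edge φ = 1/2 crossing after the relaxation
  transient.
* Problem sizes used by the shipped tests: 492–3060 quads in 2D
  (2.5–1.0 µm), 1224 hexes in 3D (4 µm, 24 µm tube), 40 pseudo-time steps
  for the scenario runs and 201×1 strips for the 1D calibrations.

## Limitations

Single homogenized wall layer (no intima/media/adventitia distinction), no
residual stress / opening angle, no blood flow or wall shear stress, no
stress feedback on growth, isotropic growth tensor only, and a
non-variational (phenomenological) phase-field source. The vasa-vasorum
geometry is a stochastic fractal idealization, not image-derived anatomy.
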