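# atherofem

A finite-element simulator of atherosclerotic artery-wall overgrowth driven
by disrupted wall nourishment ("outside-in" inflammation). The package is
aimed at computational-biomechanics researchers who want a desk-scale,
fully scriptable implementation of the coupled three-field continuum model:
mechanical deformation, nutrient transport and an inflammation phase field
on 2D annulus and 3D tube artery geometries.

## The model

Three fields live on the artery wall (lengths in µm, stresses in kPa,
pseudo-time nondimensional):

* **Deformation `u`** — quasi-static finite-strain equilibrium `∇·σ = 0` with
  a Holzapfel–Gasser–Ogden (HGO) anisotropic hyperelastic energy

  `Ψ = μ/2 (I₁ₑ−3) + η/β exp(β[ρ⟨I₄ₑ−1⟩² + (1−ρ)(I₁ₑ−3)²]) + κ_vol(J_e−1)² − μ log J_e`

  whose collagen-fiber term stiffens exponentially and only in tension
  (Macaulay bracket ⟨·⟩). Fibers wind helically,
  `n = [−cosθ_el sinθ_az, cosθ_el cosθ_az, sinθ_el]`. Inflammatory overgrowth
  enters through the multiplicative split `F = F_e F_g` with the isotropic
  growth tensor `F_g = (1+α) I`; the Gauss-point internal variable α evolves
  as `α̇/(1+α) = k_g H(α−α_cri) φ` and saturates at the critical value α_cri.
  The lumen pressure (25 mmHg ≈ 3.3 kPa, pulmonary conditions) is a follower
  load on the deformed inner surface.

* **Nutrient `c`** — steady diffusion–reaction `∇·(D(φ)∇c) − R_c = 0` with
  uniform cell consumption R_c and the inflamed-tissue diffusivity
  interpolation `D = φ D_min + (1−φ) D_max`. The wall is nourished from the
  lumen (`c = c_max` on the inner surface) and, in the outer wall, from a
  stochastic tree-fractal **vasa-vasorum** network: elements cut by the
  fractal segments receive `c = c_max`; the tree nearest a chosen arc
  coordinate can be occluded to seed the disease.

* **Inflammation `φ`** — Allen–Cahn phase field (0 healthy, 1 inflamed),

  `∂φ/∂t = −M f′(φ) + ε²∇²φ + S(φ,c)`,  `f(φ) = 16 M φ²(1−φ)²`,

  with the scarcity-seeking source `S = R_s H(c−c_cri) (∇φ·∇c)/|∇c|`: the
  lesion boundary advects with speed R_s toward nutrient-starved tissue,
  gated off where the nutrient is plentiful. A quadratic penalty (weight K_p)
  keeps φ in [0, 1].

Discretization: bilinear quads / trilinear hexes with 4 or 5 DOFs per node
(`u`, `c`, `φ`), 2×2(×2) Gauss quadrature, backward-Euler pseudo-time
stepping and a monolithic Newton–Raphson solve with a direct sparse linear
solver; α is updated per Gauss point after each converged step. See
`docs/methods.md` for conventions, parameter tables and limitations.

## Worked example

Run the canned 2D scenario with circumferential collagen fibers and an
8-tree vasa-vasorum network whose tree nearest the occlusion arc is blocked:

```bash
atherofem run --case fiber_vv --seed 0 --outdir out -v
```

prints

```
mesh: 3060 elements, 13056 DOFs
finished t=10: stenosis -5.206 %, lumen 2065.4 um^2, min c 0.8921, max phi 0.989
```

Reading the numbers: the 3.3 kPa lumen pressure dilates the fiber-reinforced
wall, so the lumen area grows from the undeformed π·25² ≈ 1963.5 µm² to
2065.4 µm² — a stenosis degree of 100·(1 − A/A₀) = −5.2 % (negative =
dilation; the tiny capped overgrowth α ≤ 10⁻³ only nudges this). `min c`
shows the mildly starved outer wall, and `max phi ≈ 0.99` the fully inflamed
lesion core that has been advected radially outward, toward scarcity, from
its mid-wall seed. The output directory contains a VTU time series
(`u`, `c`, `phi` point data; α cell data), `series.csv`
(time, lumen area, stenosis %, field extrema) and `run_log.json`
(all parameters, Newton histories, warnings, seeds).

Other entry points: `atherofem mesh` (geometry only), `atherofem vv`
(fractal network only, e.g. `--seed 0` → 8 trees, 102 segments),
`atherofem post` (stenosis-curve comparison plots from saved CSVs). The
library surface (`atherofem.Simulation`, `atherofem.fixtures.canned_case`,
…) exposes the same functionality programmatically, including the
un-coarsened `*_paper`-resolution configurations.

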