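"""Parameter groups and configuration handling.

All lengths are micrometres, stresses kilopascals, concentrations
µg·µm⁻³ and time is the nondimensional pseudo-time of the slow growth
process.  The defaults are the nominal pulmonary-artery values used
throughout the package's shipped examples.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: 1 mmHg in kPa (exact definition via the conventional mercury column).
KPA_PER_MMHG = 0.133322387415


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a blood pressure from mmHg to kPa.

    The systolic mean pressure in pulmonary arteries, 25 mmHg, converts to
    approximately 3.3 kPa, the default lumen load.
    """
    return p_mmhg * KPA_PER_MMHG


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass
class GeometryParams:
    """Artery cross-section / tube geometry (µm)."""

    inner_diameter: float = 50.0   #: lumen diameter D
    wall_thickness: float = 15.0   #: wall thickness t
    length: float = 100.0          #: axial length L (3D only)
    occlusion_arc: float = 30.0    #: arc coordinate S of the initial occlusion, on the mid-wall circle
    mesh_size: float = 0.5         #: target element edge h

    def validate(self) -> None:
        for name in ("inner_diameter", "wall_thickness", "length", "mesh_size"):
            _positive(name, getattr(self, name))
        if self.occlusion_arc < 0:
            raise ValueError("occlusion_arc must be non-negative")
        if self.mesh_size > self.wall_thickness / 3.0:
            raise ValueError(
                "mesh_size must resolve the wall with at least 3 element layers "
                f"(h={self.mesh_size} > t/3={self.wall_thickness / 3.0})"
            )

    @property
    def inner_radius(self) -> float:
        return 0.5 * self.inner_diameter

    @property
    def outer_radius(self) -> float:
        return 0.5 * self.inner_diameter + self.wall_thickness

    @property
    def mid_radius(self) -> float:
        return 0.5 * self.inner_diameter + 0.5 * self.wall_thickness


@dataclass
class MaterialParams:
    """HGO-type anisotropic hyperelastic wall material."""

    shear_modulus: float = 10.0        #: µ [kPa]
    poisson: float = 0.49              #: ν
    fiber_stiffness: float = 100.0     #: η [kPa]; 0 disables collagen fibers
    fiber_exponent: float = 1.0        #: β
    dispersion: float = 0.5            #: ρ ∈ [0, 1]
    fiber_elevation: float = math.radians(60.0)  #: helix elevation angle θ_el [rad]
    #: matrix term uses the full (non-isochoric) first invariant so the −µ log J
    #: term cancels at identity and the unloaded artery is stress free.  Set to
    #: True to evaluate the matrix term with the isochoric invariant instead.
    isochoric_matrix_term: bool = False
    #: volumetric coefficient κ_vol.  The default is the compressible
    #: neo-Hookean Lamé combination µν/(1−2ν) [kPa]; ``literal_volumetric``
    #: switches to the dimensionally odd ν/(µ(1−2ν)) variant.
    literal_volumetric: bool = False
    exp_clip: float = 50.0             #: cap on the fiber-energy exponent

    def validate(self) -> None:
        _positive("shear_modulus", self.shear_modulus)
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("poisson must lie in (0, 0.5)")
        if self.fiber_stiffness < 0:
            raise ValueError("fiber_stiffness must be >= 0")
        _positive("fiber_exponent", self.fiber_exponent)
        if not 0.0 <= self.dispersion <= 1.0:
            raise ValueError("dispersion must lie in [0, 1]")

    @property
    def kappa_vol(self) -> float:
        mu, nu = self.shear_modulus, self.poisson
        if self.literal_volumetric:
            return nu / (mu * (1.0 - 2.0 * nu))
        return mu * nu / (1.0 - 2.0 * nu)


@dataclass
class GrowthParams:
    """Inflammation-driven isotropic volumetric growth."""

    rate: float = 0.25       #: k_g [1/time]
    cap: float = 1.0e-3      #: α_cri — growth stops once α exceeds this value

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        _positive("cap", self.cap)


@dataclass
class NutrientParams:
    """Steady diffusion-reaction nutrient transport."""

    d_max: float = 1.0       #: healthy-tissue diffusivity [µm²/time]
    d_min: float = 0.1       #: inflamed-tissue diffusivity [µm²/time]
    consumption: float = 1.0e-3  #: uniform cell consumption R_c [µg µm⁻³/time]
    c_max: float = 1.0       #: blood-contact concentration [µg µm⁻³]
    c_cri: float = 1.0       #: scarcity threshold for the inflammation source

    def validate(self) -> None:
        if not self.d_max >= self.d_min > 0:
            raise ValueError("need d_max >= d_min > 0")
        if self.consumption < 0:
            raise ValueError("consumption must be >= 0")
        _positive("c_max", self.c_max)


@dataclass
class PhaseFieldParams:
    """Allen-Cahn inflammation phase field."""

    interface: float = 1.0   #: ε — interface length-scale coefficient
    barrier: float = 10.0    #: M — energy barrier between the two wells
    source_rate: float = 0.1  #: R_s — advection speed toward scarcity [µm/time]
    penalty: float = 1.0e4   #: K_p — boundedness penalty
    grad_floor: float = 1.0e-8  #: δ_g — floor on |∇c| in the source term

    def validate(self) -> None:
        _positive("interface", self.interface)
        _positive("barrier", self.barrier)
        if self.source_rate < 0 or self.penalty < 0:
            raise ValueError("source_rate and penalty must be >= 0")
        _positive("grad_floor", self.grad_floor)


@dataclass
class FractalParams:
    """Stochastic tree-fractal vasa-vasorum geometry."""

    trunk_length: float = 3.0                  #: L0 [µm]
    length_ratios: tuple = (1.0, 1.0, 1.0)     #: λ_k for levels 2..4
    branch_angles: tuple = (2.0 * math.pi / 3.0,) * 3  #: γ_k (full opening) for levels 2..4 [rad]
    azimuth_angles: tuple = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)  #: γ_az (3D)
    elevation_angles: tuple = (math.pi / 3.0,) * 3  #: γ_el (3D)
    n_trees: int = 8          #: anchors equally spaced on the outer circle
    jitter: float = 0.1       #: relative std of lengths/angles, ×(1 + jitter·N(0,1))
    seed: int = 0             #: RNG seed for the stochastic realization

    def validate(self) -> None:
        _positive("trunk_length", self.trunk_length)
        if any(l <= 0 for l in self.length_ratios):
            raise ValueError("length_ratios must be positive")
        if len(self.azimuth_angles) != len(self.elevation_angles):
            raise ValueError("azimuth_angles and elevation_angles must have equal length")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class SolverParams:
    """Monolithic Newton / backward-Euler time stepping."""

    k_c: float = 1.0            #: nutrient-block scaling K_c
    k_phi: float = 1.0          #: phase-block scaling K_φ
    dt: float = 0.05            #: pseudo-time step
    t_end: float = 20.0         #: total pseudo-time
    newton_tol: float = 1.0e-8  #: absolute residual-norm tolerance (scaled system)
    newton_max_iter: int = 25
    step_halving_max: int = 8
    p_max: float = 3.3          #: lumen pressure [kPa]
    p_ramp_time: float = 1.0    #: pressure ramped linearly over [0, p_ramp_time]
    save_every: int = 1         #: record every n-th converged step
    rng_seed: int = 0

    def validate(self) -> None:
        _positive("dt", self.dt)
        _positive("newton_tol", self.newton_tol)
        _positive("k_c", self.k_c)
        _positive("k_phi", self.k_phi)
        if self.p_max < 0:
            raise ValueError("p_max must be >= 0")


@dataclass
class SimulationConfig:
    """Everything needed to run one simulation."""

    dim: int = 2
    geometry: GeometryParams = field(default_factory=GeometryParams)
    material: MaterialParams = field(default_factory=MaterialParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    nutrient: NutrientParams = field(default_factory=NutrientParams)
    phasefield: PhaseFieldParams = field(default_factory=PhaseFieldParams)
    solver: SolverParams = field(default_factory=SolverParams)
    vasa_vasorum: FractalParams = field(default_factory=FractalParams)
    enable_vv: bool = False        #: tag VV-cut elements and nourish them
    occlude_tree: bool = True      #: drop the tree nearest the occlusion arc from the Dirichlet set
    seed_lesion: bool = True       #: place the initial inflammation seed at the occlusion site
    seed_radius: Optional[float] = None  #: lesion seed radius; default 2·mesh_size
    fix_displacement: bool = False  #: clamp u everywhere (transport-only studies)
    fix_phase: bool = False         #: clamp φ at its initial value
    freeze_nutrient: bool = False   #: clamp c at its initial value (prescribed-profile studies)
    dirichlet_c_tags: Optional[tuple] = None  #: facet tags clamped at c_max (default: inner_surface)
    label: str = "run"

    def validate(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        for group in (self.geometry, self.material, self.growth, self.nutrient,
                      self.phasefield, self.solver, self.vasa_vasorum):
            group.validate()

    @property
    def lesion_seed_radius(self) -> float:
        return 2.0 * self.geometry.mesh_size if self.seed_radius is None else self.seed_radius

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def tuples_to_lists(obj):
            if isinstance(obj, tuple):
                return [tuples_to_lists(v) for v in obj]
            if isinstance(obj, dict):
                return {k: tuples_to_lists(v) for k, v in obj.items()}
            return obj

        return tuples_to_lists(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kwargs = {}
        groups = {
            "geometry": GeometryParams,
            "material": MaterialParams,
            "growth": GrowthParams,
            "nutrient": NutrientParams,
            "phasefield": PhaseFieldParams,
            "solver": SolverParams,
            "vasa_vasorum": FractalParams,
        }
        for name, gcls in groups.items():
            if name in d:
                sub = dict(d.pop(name))
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[name] = gcls(**sub)
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> SimulationConfig:
    """The nominal parameter set (Table-2-style defaults) for a 2D cross-section."""
    return SimulationConfig()
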