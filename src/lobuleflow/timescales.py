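"""Process-timescale analysis of the lobule model.

Four competing processes set the regimes the simulations explore:
pressure relaxation (fastest), metabolic elimination, local particle
diffusion, and convective breakthrough (slowest).  This module computes
each characteristic time from the model parameters and assembles the
comparison report that rationalizes the simulated behaviour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import pandas as pd

from .fluids import FluidProperties, ReactionSpec, SpeciesSet, default_species, effective_rate
from .lattice import Lattice, pore_volumes
from .pressure import PressureSolution
from .units import DARCY_VELOCITY_FACTOR

__all__ = [
    "TimescaleReport",
    "pressure_diffusivity",
    "characteristic_time",
    "breakthrough_estimates",
    "build_report",
]

#: Characteristic pressure-equilibration distance: the lobule element
#: size (cm) seen by the pressure field.
PRESSURE_DISTANCE_CM = 0.15

#: Characteristic local-diffusion smoothing distance (10 μm, one cell
#: radius) in cm.
DIFFUSION_DISTANCE_CM = 1.0e-3


def pressure_diffusivity(
    permeability: float, porosity: float, viscosity: float, c_eff: float
) -> float:
    """Pressure diffusion coefficient D_pres = K/(φ μ C_p^eff), cm²/min.

    permeability in cm², viscosity in mPa·s, c_eff in kPa⁻¹.
    """
    if permeability <= 0 or porosity <= 0 or viscosity <= 0 or c_eff <= 0:
        raise ValueError("all pressure-diffusivity inputs must be positive")
    return DARCY_VELOCITY_FACTOR * permeability / (porosity * viscosity * c_eff)


def characteristic_time(distance: float, diffusivity: float) -> float:
    """Diffusive time T = d²/D (d in cm, D in cm²/min → T in min)."""
    if distance <= 0 or diffusivity <= 0:
        raise ValueError("distance and diffusivity must be positive")
    return distance**2 / diffusivity


def breakthrough_estimates(pore_vols: dict[str, float], inlet_rate: float) -> dict[str, float]:
    """Convective transit times: pore volume ÷ volumetric rate.

    ``sinusoid`` assumes only the sinusoid network is accessible to the
    injected species; ``total`` assumes the whole element is.
    """
    if inlet_rate <= 0:
        raise ValueError("inlet_rate must be positive")
    return {
        "sinusoid": pore_vols["sinusoid"] / inlet_rate,
        "total": pore_vols["total"] / inlet_rate,
    }


@dataclass
class TimescaleReport:
    """The assembled process-timescale comparison (all times in min)."""

    pressure_diffusivity: float          # cm²/min
    pressure_relaxation: float           # d²/D_pres
    pressure_relaxation_simulated: float | None
    diffusion_time_sinusoid: float
    diffusion_time_tissue: float
    reaction_half_life: float
    breakthrough_sinusoid: float
    breakthrough_total: float
    characteristic_distance_pressure: float = PRESSURE_DISTANCE_CM
    characteristic_distance_diffusion: float = DIFFUSION_DISTANCE_CM

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            ("pressure_diffusivity_cm2_per_min", self.pressure_diffusivity),
            ("pressure_relaxation_min", self.pressure_relaxation),
            ("diffusion_time_sinusoid_min", self.diffusion_time_sinusoid),
            ("diffusion_time_tissue_min", self.diffusion_time_tissue),
            ("reaction_half_life_min", self.reaction_half_life),
            ("breakthrough_sinusoid_min", self.breakthrough_sinusoid),
            ("breakthrough_total_min", self.breakthrough_total),
        ]
        if self.pressure_relaxation_simulated is not None:
            rows.insert(2, ("pressure_relaxation_simulated_min",
                            self.pressure_relaxation_simulated))
        return pd.DataFrame(rows, columns=["process", "time_min"])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def assert_ordering(self) -> None:
        """Base-case ordering: pressure ≪ reaction < diffusion < transit."""
        seq = [
            self.pressure_relaxation,
            self.reaction_half_life,
            self.diffusion_time_sinusoid,
            self.diffusion_time_tissue,
            self.breakthrough_sinusoid,
            self.breakthrough_total,
        ]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"timescale ordering violated: {seq}")


def build_report(
    lattice: Lattice,
    fluid: FluidProperties | None = None,
    species: SpeciesSet | None = None,
    reaction: ReactionSpec | None = None,
    flow: PressureSolution | None = None,
    simulated_pressure_relaxation: float | None = None,
) -> TimescaleReport:
    """Assemble the timescale report from the model configuration.

    ``flow`` supplies the steady inlet rate for the breakthrough
    estimates; ``simulated_pressure_relaxation`` (from the transient
    solve) is carried alongside the analytic d²/D value because the two
    differ — the report flags both rather than resolving them.
    """
    fluid = fluid if fluid is not None else FluidProperties()
    species = species if species is not None else default_species()
    reaction = reaction if reaction is not None else ReactionSpec()
    if flow is None:
        raise ValueError("build_report needs a solved steady flow for breakthrough times")

    spec = lattice.spec
    d_pres = pressure_diffusivity(
        spec.sinusoid_permeability,
        spec.sinusoid_porosity,
        fluid.viscosity,
        fluid.effective_compressibility,
    )
    t_pres = characteristic_time(PRESSURE_DISTANCE_CM, d_pres)
    drug = species.drug
    t_diff_sin = characteristic_time(DIFFUSION_DISTANCE_CM, drug.diffusion_sinusoid)
    t_diff_tis = characteristic_time(DIFFUSION_DISTANCE_CM, drug.diffusion_tissue)
    t_reac = effective_rate(reaction)["half_life"]
    bt = breakthrough_estimates(pore_volumes(lattice), flow.inlet_rate)

    return TimescaleReport(
        pressure_diffusivity=d_pres,
        pressure_relaxation=t_pres,
        pressure_relaxation_simulated=simulated_pressure_relaxation,
        diffusion_time_sinusoid=t_diff_sin,
        diffusion_time_tissue=t_diff_tis,
        reaction_half_life=t_reac,
        breakthrough_sinusoid=bt["sinusoid"],
        breakthrough_total=bt["total"],
    )
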