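"""Configuration schema, validation and loading.

One schema serves YAML and JSON.  Every field name carries its unit;
unknown keys are rejected with a message naming each offender; an empty
file (or no file) yields the full base-case defaults.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .fluids import FluidProperties, ReactionSpec, Species, SpeciesSet
from .lattice import LatticeSpec
from .pressure import BoundaryWells
from .transport import ScenarioConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised for any configuration-schema violation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LatticeBlock(_Block):
    n_side: int = 51
    sinusoid_width_cm: float = 0.0006
    boundary_sinusoid_width_cm: float = 0.0003
    tissue_width_cm: float = 0.0024
    depth_cm: float = 0.0003
    sinusoid_porosity: float = math.pi / 4.0
    sinusoid_permeability_cm2: float = 1.125e-8
    tissue_porosity: float = 0.2382
    tissue_permeability_cm2: float = 7.45e-2 * 9.869e-9
    hepatocyte_diameter_cm: float = 0.0024


class FluidBlock(_Block):
    molar_density_mmol_per_cm3: float = 55.4
    viscosity_mpa_s: float = 3.5
    fluid_compressibility_per_kpa: float = 5.0e-7
    structural_compressibility_per_kpa: float = 1.8e-5


class SpeciesBlock(_Block):
    drug_name: str = "PAC"
    drug_molecular_weight_g_per_mol: float = 854.0
    metabolite_name: str = "PAC-OH"
    metabolite_molecular_weight_g_per_mol: float = 870.0
    diffusion_sinusoid_cm2_per_min: float = 2.5e-4
    diffusion_tissue_cm2_per_min: float = 2.5e-5


class ReactionBlock(_Block):
    vmax_molfrac_per_min: float = 1.08e-9
    km_molfrac: float = 1.8e-7
    scale_factor: float = 0.76e-6
    rate_multiplier: float = 1.0


class WellsBlock(_Block):
    injector_cell: tuple[int, int] = (1, 1)
    injector_pressure_kpa: float = 103.0
    producer_cell: tuple[int, int] = (51, 51)
    producer_pressure_kpa: float = 101.8


class ScenarioBlock(_Block):
    diffusion_enabled: bool = True
    reaction_enabled: bool = False
    rate_multiplier: float = 1.0
    injected_pac_molfrac: float = 1.8e-8
    end_time_min: float = 1.0
    snapshot_times_min: tuple[float, ...] = (0.01, 0.14, 0.50)


class OutputBlock(_Block):
    directory: str = "lobuleflow_out"
    write_vtk: bool = True
    write_csv: bool = True
    max_effluent_rows: int = 2000


class RunConfig(_Block):
    """Fully-validated run configuration (all blocks defaulted)."""

    lattice: LatticeBlock = LatticeBlock()
    fluid: FluidBlock = FluidBlock()
    species: SpeciesBlock = SpeciesBlock()
    reaction: ReactionBlock = ReactionBlock()
    wells: WellsBlock = WellsBlock()
    scenario: ScenarioBlock = ScenarioBlock()
    output: OutputBlock = OutputBlock()

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        n = self.lattice.n_side
        for name, cell in (("injector_cell", self.wells.injector_cell),
                           ("producer_cell", self.wells.producer_cell)):
            if not (1 <= cell[0] <= n and 1 <= cell[1] <= n):
                raise ValueError(f"wells.{name} {cell} outside the {n}x{n} lattice")
        for t in self.scenario.snapshot_times_min:
            if not 0.0 <= t <= self.scenario.end_time_min:
                raise ValueError(
                    f"scenario.snapshot_times_min entry {t} outside "
                    f"[0, end_time_min={self.scenario.end_time_min}]"
                )
        return self

    # -- domain-object converters ------------------------------------------

    def lattice_spec(self) -> LatticeSpec:
        lb, wb = self.lattice, self.wells
        return LatticeSpec(
            n_side=lb.n_side,
            sinusoid_width=lb.sinusoid_width_cm,
            boundary_sinusoid_width=lb.boundary_sinusoid_width_cm,
            tissue_width=lb.tissue_width_cm,
            depth=lb.depth_cm,
            sinusoid_porosity=lb.sinusoid_porosity,
            sinusoid_permeability=lb.sinusoid_permeability_cm2,
            tissue_porosity=lb.tissue_porosity,
            tissue_permeability=lb.tissue_permeability_cm2,
            hepatocyte_diameter=lb.hepatocyte_diameter_cm,
            inlet_cell=tuple(wb.injector_cell),
            outlet_cell=tuple(wb.producer_cell),
        )

    def fluid_properties(self) -> FluidProperties:
        fb = self.fluid
        return FluidProperties(
            molar_density=fb.molar_density_mmol_per_cm3,
            viscosity=fb.viscosity_mpa_s,
            fluid_compressibility=fb.fluid_compressibility_per_kpa,
            structural_compressibility=fb.structural_compressibility_per_kpa,
        )

    def species_set(self) -> SpeciesSet:
        sb = self.species
        drug = Species(
            name=sb.drug_name,
            molecular_weight=sb.drug_molecular_weight_g_per_mol,
            diffusion_sinusoid=sb.diffusion_sinusoid_cm2_per_min,
            diffusion_tissue=sb.diffusion_tissue_cm2_per_min,
        )
        met = Species(
            name=sb.metabolite_name,
            molecular_weight=sb.metabolite_molecular_weight_g_per_mol,
            diffusion_sinusoid=sb.diffusion_sinusoid_cm2_per_min,
            diffusion_tissue=sb.diffusion_tissue_cm2_per_min,
        )
        return SpeciesSet(drug=drug, metabolite=met)

    def reaction_spec(self) -> ReactionSpec:
        rb = self.reaction
        return ReactionSpec(
            v_max=rb.vmax_molfrac_per_min,
            K_m=rb.km_molfrac,
            scale_factor=rb.scale_factor,
            rate_multiplier=rb.rate_multiplier,
        )

    def boundary_wells(self) -> BoundaryWells:
        wb = self.wells
        return BoundaryWells(
            injector_cell=tuple(wb.injector_cell),
            injector_pressure=wb.injector_pressure_kpa,
            producer_cell=tuple(wb.producer_cell),
            producer_pressure=wb.producer_pressure_kpa,
        )

    def scenario_config(self) -> ScenarioConfig:
        sb = self.scenario
        return ScenarioConfig(
            diffusion_enabled=sb.diffusion_enabled,
            reaction_enabled=sb.reaction_enabled,
            rate_multiplier=sb.rate_multiplier,
            injected_pac=sb.injected_pac_molfrac,
            end_time=sb.end_time_min,
            snapshot_times=tuple(sb.snapshot_times_min),
        )


def _format_validation_error(exc: ValidationError) -> str:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        if err["type"] == "extra_forbidden":
            msgs.append(f"unknown key: {loc}")
        else:
            msgs.append(f"{loc}: {err['msg']}")
    return "invalid configuration: " + "; ".join(msgs)


def _deep_update(base: dict, patch: dict) -> dict:
    out = dict(base)
    for k, v in patch.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def config_from_mapping(data: dict[str, Any] | None) -> RunConfig:
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config file.

    ``path=None`` or an empty file yields full base-case defaults.
    ``overrides`` is a nested mapping merged on top of the file content.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    if overrides:
        data = _deep_update(data, overrides)
    return config_from_mapping(data)


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize the fully-resolved config as JSON (also valid YAML)."""
    text = json.dumps(config.model_dump(), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
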