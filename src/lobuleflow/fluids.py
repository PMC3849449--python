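"""Fluid, species and reaction parameters with unit conversions.

Blood is treated as water: molar density ρ = 55.4 mmol/cm³, viscosity
μ = 3.5 mPa·s.  Drug concentrations are carried as mole fractions
x = C/ρ.  The drug is paclitaxel (PAC, MW 854 g/mol); its Phase-I
metabolite 6-hydroxypaclitaxel (PAC-OH) inherits PAC's transport
coefficients.  Elimination is one-step saturable Michaelis–Menten
catalysed by CYP2C8 in hepatocyte (tissue) cells only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "FluidProperties",
    "Species",
    "SpeciesSet",
    "ReactionSpec",
    "molar_to_fraction",
    "fraction_to_molar",
    "rescale_diffusion",
    "effective_rate",
]


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-fluid (blood ≈ water) properties.

    molar_density : mmol/cm³; viscosity : mPa·s;
    compressibilities : kPa⁻¹ (fluid = water ~5e-7; structural = soft
    liver tissue ~1.8e-5; their sum drives pressure transients).
    """

    molar_density: float = 55.4
    viscosity: float = 3.5
    fluid_compressibility: float = 5.0e-7
    structural_compressibility: float = 1.8e-5

    def __post_init__(self) -> None:
        for name in (
            "molar_density",
            "viscosity",
            "fluid_compressibility",
            "structural_compressibility",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_compressibility(self) -> float:
        """C_p^eff = fluid + structural compressibility, kPa⁻¹."""
        return self.fluid_compressibility + self.structural_compressibility


@dataclass(frozen=True)
class Species:
    """A transported species with effective diffusivities per cell type.

    Diffusivities are in cm²/min and are *effective* values (tortuosity
    already folded in), so they are applied per cell type without an
    additional porosity factor.
    """

    name: str
    molecular_weight: float
    diffusion_sinusoid: float = 2.5e-4
    diffusion_tissue: float = 2.5e-5

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.diffusion_sinusoid < 0 or self.diffusion_tissue < 0:
            raise ValueError("diffusion coefficients must be non-negative")


def default_species() -> "SpeciesSet":
    pac = Species(name="PAC", molecular_weight=854.0)
    pacoh = Species(name="PAC-OH", molecular_weight=870.0,
                    diffusion_sinusoid=pac.diffusion_sinusoid,
                    diffusion_tissue=pac.diffusion_tissue)
    return SpeciesSet(drug=pac, metabolite=pacoh)


@dataclass(frozen=True)
class SpeciesSet:
    """The drug / metabolite pair tracked by the transport solver."""

    drug: Species
    metabolite: Species

    @property
    def names(self) -> tuple[str, str]:
        return (self.drug.name, self.metabolite.name)


@dataclass(frozen=True)
class ReactionSpec:
    """Michaelis–Menten elimination PAC → PAC-OH localized in tissue cells.

    v_max : mole-fraction/min (Table default 1.08e-9, i.e. 0.06 μM/min);
    K_m : mole fraction (1.8e-7, i.e. 10 μM);
    scale_factor : dimensionless tissue-to-bulk volume factor SF applied
        to v_max inside the solver, so the effective linear rate is
        k_eff = v_max·rate_multiplier/(K_m·SF);
    rate_multiplier : sensitivity dial (1, 1e-2, 1e-3).
    """

    v_max: float = 1.08e-9
    K_m: float = 1.8e-7
    scale_factor: float = 0.76e-6
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_max", "K_m", "scale_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be positive")

    @property
    def linear_rate(self) -> float:
        """Unscaled linear rate k = v_max/K_m, min⁻¹ (6.0e-3 at defaults)."""
        return self.v_max / self.K_m

    @property
    def v_max_effective(self) -> float:
        """SF-scaled saturable maximum rate used by the solver."""
        return self.v_max * self.rate_multiplier / self.scale_factor

    def with_multiplier(self, rate_multiplier: float) -> "ReactionSpec":
        return replace(self, rate_multiplier=rate_multiplier)


# ---------------------------------------------------------------------------
# conversions


def molar_to_fraction(concentration_um: float, fluid: FluidProperties) -> float:
    """Convert a concentration in μM to a mole fraction, x = C/ρ.

    With ρ = 55.4 mmol/cm³ = 5.54e7 μM, 10 μM → 1.8e-7 mole fraction.
    Also applies to rates (μM/min → mole-fraction/min).
    """
    if concentration_um < 0:
        raise ValueError("concentration must be non-negative")
    rho_um = fluid.molar_density * 1.0e6  # mmol/cm³ → μmol/L (= μM)
    return concentration_um / rho_um


def fraction_to_molar(mole_fraction: float, fluid: FluidProperties) -> float:
    """Inverse of :func:`molar_to_fraction` (mole fraction → μM)."""
    if mole_fraction < 0:
        raise ValueError("mole fraction must be non-negative")
    return mole_fraction * fluid.molar_density * 1.0e6


def rescale_diffusion(
    reference_D: float,
    reference_MW: float,
    target_MW: float,
    exponent: float = 0.33,
) -> float:
    """Rescale a reference diffusivity by a molecular-weight power law.

    D_target = D_ref · (MW_ref / MW_target)^exponent.  The default
    exponent 0.33 is the cube-root (Stokes–Einstein volume) scaling used
    to derive the drug diffusivity from the glucose reference value
    7.1e-10 m²/s.
    """
    if reference_D <= 0 or reference_MW <= 0 or target_MW <= 0:
        raise ValueError("diffusivity and molecular weights must be positive")
    return reference_D * (reference_MW / target_MW) ** exponent


def effective_rate(reaction: ReactionSpec) -> dict[str, float]:
    """Effective first-order elimination rate and half-life.

    half_life = SF·ln2 / (k·rate_multiplier) with k = v_max/K_m;
    k_eff = ln2/half_life.  At defaults the half-life is ≈8.8e-5 min —
    far shorter than the ≈0.2–0.3 min convective transit, which is why
    the base case converts essentially all drug.
    """
    k = reaction.linear_rate * reaction.rate_multiplier
    half_life = reaction.scale_factor * math.log(2.0) / k
    return {"k_eff": math.log(2.0) / half_life, "half_life": half_life}
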