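"""Quarter-lobule lattice geometry.

The functional unit of the liver (the lobule) is modelled as one
quarter-symmetry element of a square lattice: wide low-porosity tissue
(hepatocyte) cells interlaced with narrow high-porosity sinusoid channels.
Blood enters at one corner (terminal portal venule) and leaves at the
opposite corner (terminal hepatic venule).

Cell-type rule (1-based indices): cell (i, j) is tissue iff both i and j
are even; every other cell belongs to a sinusoid channel, so channels run
across the full lattice in both directions and cross at sinusoid-typed
intersections.  The bounding channels (rows/columns 1 and n) are half
width because the neighbouring symmetry elements carry the other half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import DARCY_TO_CM2, UM2_TO_CM2

__all__ = [
    "LatticeSpec",
    "Lattice",
    "cylinder_in_cube_porosity",
    "tube_permeability",
    "ideal_sphere_packing_porosity",
    "carman_kozeny_permeability",
    "build_lattice",
    "pore_volumes",
    "lattice_to_dataframe",
]


# ---------------------------------------------------------------------------
# property formulas


def cylinder_in_cube_porosity(vessel_radius: float) -> float:
    """Porosity of a cylindrical vessel of radius ``a`` inscribed in a cubic
    grid cell of edge ``2a``: φ = πa²(2a)/(2a)³ = π/4, independent of scale.

    Parameters
    ----------
    vessel_radius : float
        Vessel radius, any length unit, must be > 0.
    """
    if vessel_radius <= 0:
        raise ValueError(f"vessel_radius must be positive, got {vessel_radius}")
    return math.pi / 4.0


def tube_permeability(vessel_radius: float) -> float:
    """Permeability of a cylindrical tube, K = a²/8 (Poiseuille).

    Units follow the input: radius in μm gives K in μm², radius in cm
    gives K in cm².
    """
    if vessel_radius < 0:
        raise ValueError(f"vessel_radius must be non-negative, got {vessel_radius}")
    return vessel_radius**2 / 8.0


def ideal_sphere_packing_porosity(radius_to_cell_ratio: float) -> float:
    """Porosity of a spherical cell of radius R centred in a cubic grid cell
    of edge L: φ = 1 − (4π/3)(R/L)³.

    Valid for 0 ≤ R/L ≤ 0.5 (sphere fully inscribed); R/L = 0.5 gives the
    ideal hepatocyte-packing porosity 0.4764.
    """
    r = radius_to_cell_ratio
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"radius_to_cell_ratio must be in [0, 0.5], got {r}")
    return 1.0 - (4.0 * math.pi / 3.0) * r**3


def carman_kozeny_permeability(particle_diameter: float, porosity: float) -> float:
    """Carman–Kozeny permeability of a bed of spheres of diameter D_p:

        K = D_p² φ³ / (180 (1 − φ)²)

    Units of the result follow ``particle_diameter`` squared.
    """
    if particle_diameter <= 0:
        raise ValueError(f"particle_diameter must be positive, got {particle_diameter}")
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    return particle_diameter**2 * porosity**3 / (180.0 * (1.0 - porosity) ** 2)


# ---------------------------------------------------------------------------
# lattice construction


@dataclass
class LatticeSpec:
    """Geometry and material properties of the quarter-lobule lattice.

    Lengths in cm, permeabilities in cm².  Defaults are the base-case
    lobule: a 51×51 grid, 6 μm sinusoid channels (3 μm at the bounding
    rows/columns), 24 μm hepatocyte cells, 0.0750 cm per side.
    """

    n_side: int = 51
    sinusoid_width: float = 0.0006
    boundary_sinusoid_width: float = 0.0003
    tissue_width: float = 0.0024
    depth: float = 0.0003
    sinusoid_porosity: float = math.pi / 4.0
    sinusoid_permeability: float = 1.125 * UM2_TO_CM2
    tissue_porosity: float = 0.2382
    tissue_permeability: float = 7.45e-2 * DARCY_TO_CM2
    hepatocyte_diameter: float = 0.0024
    inlet_cell: tuple[int, int] = (1, 1)
    outlet_cell: tuple[int, int] = (51, 51)

    def validate(self) -> None:
        if self.n_side < 3 or self.n_side % 2 == 0:
            raise ValueError(
                f"n_side must be odd and >= 3 (sinusoid channels bound the "
                f"lattice on all sides), got {self.n_side}"
            )
        for name in ("sinusoid_width", "boundary_sinusoid_width", "tissue_width", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sinusoid_porosity", "tissue_porosity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("sinusoid_permeability", "tissue_permeability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def side_length(self) -> float:
        """Total side length in cm (sum of alternating column widths)."""
        # positions 1..n: odd are sinusoid (ends half width), even are tissue
        n_tis = (self.n_side - 1) // 2
        n_sin_full = (self.n_side + 1) // 2 - 2
        return (
            2 * self.boundary_sinusoid_width
            + n_sin_full * self.sinusoid_width
            + n_tis * self.tissue_width
        )


@dataclass
class Lattice:
    """Realized lattice: per-cell widths, types, porosity, permeability.

    Arrays are indexed ``[i, j]`` with ``i`` the row (y) and ``j`` the
    column (x), 0-based internally; all user-facing indices are 1-based.
    ``tissue_mask`` is True for hepatocyte cells.
    """

    spec: LatticeSpec
    widths: np.ndarray          # (n,) cm, identical along x and y
    tissue_mask: np.ndarray     # (n, n) bool
    porosity: np.ndarray        # (n, n)
    permeability: np.ndarray    # (n, n) cm²
    depth: float                # cm
    centers: np.ndarray = field(repr=False, default=None)  # (n,) cm

    def __post_init__(self) -> None:
        if self.centers is None:
            edges = self.edges
            self.centers = 0.5 * (edges[:-1] + edges[1:])

    @property
    def n(self) -> int:
        return len(self.widths)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.widths)])

    @property
    def side_length(self) -> float:
        return float(self.widths.sum())

    @property
    def bulk_volume(self) -> np.ndarray:
        """Per-cell bulk volume, cm³."""
        return np.outer(self.widths, self.widths) * self.depth

    @property
    def pore_volume(self) -> np.ndarray:
        """Per-cell fluid-accessible volume, cm³."""
        return self.bulk_volume * self.porosity

    @property
    def effective_permeability(self) -> np.ndarray:
        """Cell-scale (bulk) permeability used by the flow solver, cm².

        The tabulated sinusoid permeability a²/8 is a pore-scale value
        (Poiseuille flow inside the open vessel); only the open fraction
        φ of a sinusoid grid-cell face conducts, so homogenizing to the
        cell scale multiplies by porosity.  The tissue (Carman–Kozeny)
        permeability is already a bulk bed-scale value and is used as
        is.
        """
        return np.where(
            self.tissue_mask, self.permeability, self.permeability * self.porosity
        )


def build_lattice(spec: LatticeSpec | None = None) -> Lattice:
    """Construct the lattice from a spec (default: base-case lobule).

    Widths along each axis follow the alternating pattern
    [half-sinusoid, tissue, sinusoid, tissue, …, sinusoid, tissue,
    half-sinusoid]; properties are assigned by cell type with sinusoid
    properties at channel crossings.
    """
    if spec is None:
        spec = LatticeSpec()
    spec.validate()
    n = spec.n_side

    widths = np.empty(n)
    for k in range(n):  # k is 0-based; 1-based index k+1
        if k == 0 or k == n - 1:
            widths[k] = spec.boundary_sinusoid_width
        elif (k + 1) % 2 == 0:
            widths[k] = spec.tissue_width
        else:
            widths[k] = spec.sinusoid_width

    odd = (np.arange(n) + 1) % 2 == 0  # True where 1-based index is even
    tissue_mask = np.outer(odd, odd)

    porosity = np.where(tissue_mask, spec.tissue_porosity, spec.sinusoid_porosity)
    permeability = np.where(
        tissue_mask, spec.tissue_permeability, spec.sinusoid_permeability
    )
    return Lattice(
        spec=spec,
        widths=widths,
        tissue_mask=tissue_mask,
        porosity=porosity,
        permeability=permeability,
        depth=spec.depth,
    )


def pore_volumes(lattice: Lattice) -> dict[str, float]:
    """Fluid (pore) volume split by cell type, in cm³.

    Returns a dict with keys ``sinusoid``, ``tissue``, ``total``;
    sinusoid + tissue = total by construction.
    """
    pv = lattice.pore_volume
    tis = float(pv[lattice.tissue_mask].sum())
    sin = float(pv[~lattice.tissue_mask].sum())
    return {"sinusoid": sin, "tissue": tis, "total": sin + tis}


def refine_lattice(lattice: Lattice) -> Lattice:
    """Split every cell 2×2, keeping the property map (for grid studies)."""
    spec = lattice.spec
    widths = np.repeat(lattice.widths / 2.0, 2)
    tissue = np.repeat(np.repeat(lattice.tissue_mask, 2, axis=0), 2, axis=1)
    poro = np.repeat(np.repeat(lattice.porosity, 2, axis=0), 2, axis=1)
    perm = np.repeat(np.repeat(lattice.permeability, 2, axis=0), 2, axis=1)
    return Lattice(
        spec=spec,
        widths=widths,
        tissue_mask=tissue,
        porosity=poro,
        permeability=perm,
        depth=lattice.depth,
    )


def lattice_to_dataframe(lattice: Lattice) -> pd.DataFrame:
    """Per-cell property table (1-based i, j; lengths cm, volumes cm³)."""
    n = lattice.n
    ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    bulk = lattice.bulk_volume
    return pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_center_cm": np.broadcast_to(lattice.centers, (n, n)).ravel(),
            "y_center_cm": np.broadcast_to(lattice.centers[:, None], (n, n)).ravel(),
            "dx_cm": np.broadcast_to(lattice.widths, (n, n)).ravel(),
            "dy_cm": np.broadcast_to(lattice.widths[:, None], (n, n)).ravel(),
            "type": np.where(lattice.tissue_mask, "tissue", "sinusoid").ravel(),
            "porosity": lattice.porosity.ravel(),
            "permeability_cm2": lattice.permeability.ravel(),
            "bulk_volume_cm3": bulk.ravel(),
            "pore_volume_cm3": (bulk * lattice.porosity).ravel(),
        }
    )
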