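# Methods

## Model overview

`lobuleflow` simulates hepatic drug elimination on an idealized liver
lobule. The functional unit is a quarter-symmetry element of the
classic hexagonal lobule, represented as a 51×51 rectilinear lattice of
porous grid cells: wide, low-porosity **tissue** cells (hepatocytes plus
their space of Disse) interlaced by narrow, high-porosity **sinusoid**
channels that cross the element in both directions. Blood enters at one
corner (the terminal portal venule, a fixed-pressure "injector" cell)
and leaves at the opposite corner (the terminal hepatic venule, the
"producer"). Three processes compete on this lattice:

1. **Darcy flow.** Single-phase, incompressible at steady state;
   volumetric face fluxes follow a two-point flux approximation with
   distance-weighted harmonic permeability averaging. The transient
   variant adds a storage term `V_pore · C_p^eff · dp/dt` and steps with
   backward Euler on a geometrically growing time-step ramp.
2. **Species transport.** The drug (paclitaxel, PAC) and its Phase-I
   metabolite (6-hydroxypaclitaxel, PAC-OH) are carried as mole
   fractions in a constant-density fluid. Advection is single-point
   upwind on the solved face fluxes; Fickian exchange between adjacent
   cells uses per-cell-type effective diffusivities, harmonically
   averaged at faces.
3. **Metabolism.** A one-step saturable conversion PAC → PAC-OH
   (CYP2C8-catalysed) localized in tissue cells, with Michaelis–Menten
   rate `v_max_eff · x/(K_m + x)`.

## Geometry and cell properties

Cell widths alternate [half-sinusoid, tissue, sinusoid, tissue, …,
half-sinusoid]: 26 sinusoid positions (3 μm at the two boundaries, 6 μm
inside) and 25 tissue positions (24 μm) per axis, 0.0750 cm per side.
A cell is tissue iff both of its 1-based indices are even; channel
crossings keep sinusoid properties, so sinusoids form connected paths
in both directions.

Property formulas (all exposed as library functions):

- sinusoid porosity: cylinder of radius `a` inscribed in a cube of edge
  `2a`, φ = π/4 (scale-invariant);
- sinusoid permeability: open-tube (Poiseuille) value `K = a²/8`
  (1.125 μm² at a = 3 μm);
- ideal tissue porosity: sphere inscribed in a cubic cell,
  φ = 1 − (4π/3)(R/L)³ = 0.4764 at R/L = ½;
- tissue permeability: Carman–Kozeny,
  `K = D_p² φ³/(180(1−φ)²)` (1.262 μm² at the ideal porosity).

Defaults use the *base-case* tissue values φ = 0.2382 and
K = 7.45×10⁻² Darcy (the halved-porosity row of the source parameter
set) rather than the ideal-packing values, because extracellular matrix
reduces the ideal porosity.

**Grid depth.** The third dimension is not part of the published
geometry; 0.0003 cm is the unique depth that reproduces the published
sinusoid pore volume (4.77×10⁻⁷ cm³) and total pore volume
(7.344×10⁻⁷ cm³) with the stated porosities. It is a configuration
field.

**Permeability homogenization.** The tube formula `a²/8` describes flow
*inside* the open vessel, so at the grid-cell scale only the open
fraction of a sinusoid cell face conducts and the solver uses
`φ_sin · K_sin` for sinusoid cells (`Lattice.effective_permeability`).
The Carman–Kozeny tissue value is already a bulk bed-scale permeability
and is used as is. This choice reproduces the published steady inflow
(2.56×10⁻⁶ vs 2.44×10⁻⁶ cm³/min, +5%) where the un-homogenized value
overshoots by 27%.

## Units

Internal units: cm, min, kPa, mPa·s, mole fraction; permeability in cm²
(1 Darcy = 9.869×10⁻⁹ cm²). The single nontrivial conversion constant
is `K[cm²]·Δp[kPa]/(μ[mPa·s]·L[cm]) → cm/min`, factor 6×10⁷.
Laboratory concentrations convert as x = C/ρ with blood molar density
ρ = 55.4 mmol/cm³ (10 μM ↔ 1.8×10⁻⁷ mole fraction).

## Key parameters

| Parameter | Default | Unit | Meaning |
|---|---|---|---|
| P_in / P_out | 103 / 101.8 | kPa | injector / producer pressures |
| μ | 3.5 | mPa·s | blood viscosity |
| C_p^eff | 5×10⁻⁷ + 1.8×10⁻⁵ | kPa⁻¹ | fluid + structural compressibility |
| D_sin / D_tis | 2.5×10⁻⁴ / 2.5×10⁻⁵ | cm²/min | effective diffusivities |
| v_max | 1.08×10⁻⁹ | molfrac/min | Michaelis–Menten maximum rate |
| K_m | 1.8×10⁻⁷ | molfrac | half-saturation level |
| SF | 0.76×10⁻⁶ | – | tissue-to-bulk volume scale factor |
| x_inj | 1.8×10⁻⁸ | molfrac | injected drug level (base case) |

The drug diffusivity derives from the glucose reference
(7.1×10⁻¹⁰ m²/s, MW 180) by cube-root molecular-weight rescaling to
MW 854, giving 4.2×10⁻¹⁰ m²/s in sinusoids and a further order of
magnitude reduction in tissue.

**The scale factor SF.** The raw linear rate k = v_max/K_m =
6×10⁻³ min⁻¹ gives a half-life of ≈115 min — far longer than the
0.2–0.3 min transit, under which essentially no conversion could occur.
The solver therefore uses the SF-scaled maximum rate
`v_max·multiplier/SF`, whose linear-regime half-life is
SF·ln2/k ≈ 8.8×10⁻⁵ min. This scaled form reproduces the published
regime structure: complete conversion at base rate, partial at 100×
reduction, comparable drug/metabolite effluents at 1000× reduction.
SF does not correspond to an obvious volume ratio of the stated
geometry and is treated as an empirical calibration constant; it is a
configuration field, so the unscaled interpretation is also runnable.

## Numerics

- **Steady pressure**: direct sparse solve (UMFPACK-family LU via
  SciPy); Dirichlet rows at the two well cells; residual checked below
  10⁻¹⁰ relative. Global mass balance closes to <10⁻⁸ and the discrete
  maximum principle holds by construction (M-matrix).
- **Transient pressure**: backward Euler, first step 10⁻⁹ min, step
  ratio 1.05 (chosen by checking the settle-time changes < a few
  percent against ratio 1.02). Settle time is defined as the first
  time the inlet rate is within 1% of steady, linearly interpolated
  between steps.
- **Transport**: explicit Euler on the assembled sparse
  advection+diffusion operator, step capped at 0.9× the cell CFL limit
  (min pore volume over total outflow+exchange). The limiting cell is
  the 3×3 μm injector corner (residence ≈8×10⁻⁶ min), giving ≈1.4×10⁵
  steps per simulated minute; a full scenario runs in tens of seconds.
  Requests for larger steps sub-step automatically.
- **Reaction**: integrated exactly over each sub-step with the
  Lambert-W closed form of the Michaelis–Menten ODE — unconditionally
  stable (the base-rate half-life of 10⁻⁴ min is stiff for naive
  stepping) and correct in both the linear and saturated regimes.
  Conversion applies in tissue cells only, with exact 1:1 stoichiometry
  to the metabolite.
- **Accounting**: injected, produced and converted moles are tallied
  from the same face fluxes the update uses, so closure
  (injected = produced + in-place + converted) holds to machine
  precision; the suite asserts <10⁻⁸ relative in every scenario.
- Upwind advection carries first-order numerical dispersion; this is
  accepted — the reference simulations exhibit comparable mixing, and
  tracer fronts are interpreted with that in mind.

## Timescale analysis

The module reproduces the process-timescale comparison: pressure
diffusivity D_pres = K/(φμC_p^eff) ≈ 1.3×10⁴ cm²/min; pressure
relaxation d²/D_pres ≈ 1.7×10⁻⁶ min over the d = 0.15 cm element;
particle diffusion times d²/D of 4×10⁻³ (sinusoid) and 4×10⁻² min
(tissue) over 10 μm; reaction half-life 8.8×10⁻⁵ min; convective
breakthrough as pore volume over flow rate (0.186 min sinusoid-only,
0.286 min whole element). The report also carries the *simulated*
transient settle time (≈7×10⁻⁶ min) alongside the analytic estimate:
the two differ, as do the published values for this quantity
(1.5×10⁻⁶–2×10⁻⁵ min depending on where it is read), and the report
flags both rather than reconciling them.

## Known limitations and open discrepancies

- **Breakthrough half-rise.** The simulated non-reactive half-rise with
  the base tissue properties is ≈0.25 min, between the sinusoid-only
  (0.186) and whole-element (0.286) limits, because the tissue —
  conductive and diffusively coupled — retards the front. The reference
  work reports 0.19 min, *below* its own sinusoid-only limit, which is
  only possible if the tracer does not sample the tissue pore volume at
  all; with the stated tissue porosity, permeability and diffusivity on
  24 μm cells, that uptake is unavoidable. Relatedly, a tissue
  permeability ~10³ lower than the base value reproduces the published
  flow rate to 0.04% and the "orders of magnitude" sinusoid/tissue
  velocity contrast, but then tissue cannot fill convectively on the
  0.1–0.5 min scale shown in the published no-diffusion concentration
  maps. These observations cannot be satisfied simultaneously; the
  package keeps the published base parameters and documents the
  difference.
- Sinusoid vs tissue median superficial speed contrast is ≈7.5× (not
  orders of magnitude) under the base parameters.
- The hepatic-artery contribution (pulsatile, smaller volume) is
  omitted; wells are fixed-pressure cells without a well-index model.
- Blood is Newtonian with constant density; dilute species do not feed
  back on the flow.
- Enzyme zonation, multi-step uptake kinetics, enzyme depletion and
  micellar drug complexation are out of scope; diffusivities assume
  molecular dissolution and are upper bounds.
- The tool is fully deterministic — there is no random number
  generation anywhere, so repeated runs are byte-identical.

## Scenario presets

`base_nonreactive[_nodiff]`, `base_reactive[_nodiff]`,
`reactive_100x_reduced`, `reactive_1000x_reduced` (rate multipliers
10⁻², 10⁻³) and `concentration_sweep` (injected levels 1.8×10⁻⁸ —
linear regime, 1.8×10⁻⁷ = K_m, 1.8×10⁻⁶ — saturated; diffusion off).
Default end time 1.0 min with snapshots at 0.01, 0.14 and 0.50 min.
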