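# Methods

## Scope and units

The package post-processes reaction energetics: all Gibbs free energies
enter in kcal mol⁻¹ referenced to the 1 M standard state at the stated
temperature (default 298.15 K), rate constants leave in M⁻¹ s⁻¹, and the
diffusion arithmetic is done in SI internally. Every conversion goes
through `radscav.constants` (CODATA 2018 exact values;
k_B·T/h = 6.2124×10¹² s⁻¹ at 298.15 K, asserted in the unit tests). A
helper applies the 1 atm → 1 M correction (ΔnRT·ln R′T, ≈1.89 kcal mol⁻¹
per mole change at room temperature) for users whose barriers come
directly from gas-phase thermochemistry output; the bundled tables are
already on the 1 M scale.

## Screening

Viability is the strict inequality ΔG° < threshold with threshold 0 by
default (configurable for sensitivity analysis); a boundary channel with
ΔG° = 0 is nonviable. SET channels are never rated kinetically: a SET rate
constant would require a reorganization energy, which is not part of the
channel-table contract, so SET participates in screening only. Screening
is a pure filter — it partitions its input in order and never alters
channel parameters.

## TST rate model

k = σ·κ·(k_B T/h)·exp(−ΔG‡/RT), conventional transition-state theory with
a transmission coefficient. The reaction-path degeneracy σ is explicit
per-channel data, never inferred from structure: for the bundled
gas-phase table the methyl-type FHT rows only reconstruct the tabulated
rates with σ = 3, while the solution-phase FHT row is consistent with
σ = 1; both readings are recorded in the fixtures as data.

Tunneling modes:

* **supplied** (default) — κ consumed as data. This is the mode used for
  all reproductions of the bundled tables, whose κ values (1.0–5.2) are
  given without their derivation inputs.
* **wigner** — κ = 1 + u²/24 with u = hcν‡/(k_B T); a small-curvature
  fallback needing only the imaginary frequency.
* **eckart** — κ = exp(V_f/RT)/(RT) · ∫₀^∞ P(E)·exp(−E/RT) dE with P(E)
  the two-parameter asymmetric-Eckart transmission probability fixed by
  (V_f, V_r, ν‡). P(E) = 0 below the product asymptote max(0, V_f − V_r).
  The cosh expressions are evaluated in log space so large-barrier /
  low-frequency regimes cannot overflow; integration is adaptive
  quadrature on E ∈ [0, V_f + 40·RT] at relative tolerance 1e-8 with a
  breakpoint at the barrier top (the integrand decays as exp(−E/RT), so
  the truncated tail is ~e⁻⁴⁰ of the classical flux). The integrator is
  validated against a 10⁵-point fixed-grid trapezoid oracle (1e-6
  relative) and against the Wigner limit at small curvature (κ_Eckart and
  κ_Wigner agree to 1.4% for a symmetric 5 kcal mol⁻¹ barrier at
  300 cm⁻¹).

## Diffusion correction and aggregation

Solution-phase apparent rates use Stokes–Einstein diffusion coefficients,
the Smoluchowski encounter rate k_D = 4π·R_AB·(D_A + D_B)·N_A (R_AB
defaulting to the sum of the Stokes radii) and the Collins–Kimball
interpolation k_app = k_D·k_act/(k_D + k_act). Gas phase is represented as
k_D = ∞ (no correction applied), not as a large finite number, so the
k_app = k_act contract is exact. Branching ratios Γᵢ = 100·k_app,i/Σk_app
are kept at full precision internally and rounded to one decimal only in
report writers; k_overall is the plain sum of apparent rates.

For pentyl ethanoate the conditions file records η = 8.62×10⁻⁴ Pa·s
(standard solvent tables, 298.15 K) and Stokes radii of 5.0 Å (solute,
from its molar volume) and 2.0 Å (HO•), giving k_D ≈ 9.4×10⁹ M⁻¹ s⁻¹.
Note a known reconstruction gap: the bundled solution-phase apparent
rates for the two fast channels imply an effective encounter rate of
~2.5×10⁹ M⁻¹ s⁻¹, smaller than any value Stokes–Einstein can produce at
this viscosity (the minimum over radii is ~7.7×10⁹). The diffusion inputs
behind those reference numbers are not recorded with them; this package
therefore treats the printed apparent rates as data for aggregation
checks, while its own diffusion stack uses the documented physical
defaults. The slow C13 channel is activation-controlled and insensitive
to k_D anywhere above 10⁹ M⁻¹ s⁻¹.

## DPPH assay

SP% = 100·(OD₀ − OD₁)/OD₀; the statistic may be negative (pro-oxidant
wells) and is clamped only in reports. Replicates are aggregated as
mean ± sd per concentration with uniform weights before fitting. When the
maximum mean SP reaches 50%, EC50 comes from a least-squares
four-parameter logistic with bottom fixed at 0, top free on (0, 100] and
Hill slope bounded at 15 (beyond which the curve is a step on any
realistic dilution ladder); otherwise the result is censored and labeled
"> C". The censoring label's concentration defaults to the largest tested
concentration, with an explicit `report_threshold` parameter because
published tables sometimes quote the censoring bound against a chosen
benchmark concentration rather than the top of the tested ladder; the
bundled plate reproduction passes 128 µg mL⁻¹, matching its table's
convention. The EC50 estimation model behind published single-number
EC50s is generally unstated, so numeric cross-checks against external
values are bracketing checks, not equalities. Mass↔molar conversion is
exact arithmetic: µg mL⁻¹ / (g mol⁻¹) = mM.

## Geometry

All metrics are functions of internal coordinates only and therefore
rigid-motion invariant by construction (asserted to 1e-9). The mean plane
is the least-squares plane through the centroid, obtained from the SVD of
the centered coordinates (normal = singular vector of the smallest
singular value); its r.m.s. deviation equals σ_min/√n, cross-checked in
tests against an independent eigen-decomposition and a spherical-grid
search oracle. Inter-plane angles are reported acute ([0°, 90°]), the
crystallographic convention. Structure comparison evaluates per-bond and
per-angle absolute and percent deviations with the reference (crystal)
value as denominator and performs no superposition. Crystal-structure
ingestion is via user-exported XYZ; CIF parsing and any download of
deposited coordinates are out of scope, so tests use constructive
synthetic geometries (rings built at known inter-plane angles,
hydrogen-bond triangles built by inverse geometry from chosen distances
and angle).

## Synthetic data

Generators exist so that every stage is testable offline, with all
randomness through one explicitly seeded numpy Generator:

* **Channel sets** — ΔG° uniform on [−25, 15] kcal mol⁻¹ (the span of
  typical FHT/RAF tables), barriers from a Bell–Evans–Polanyi-type linear
  free-energy relation ΔG‡ = 10 + 0.4·ΔG° + ε (ε Gaussian, sd
  1 kcal mol⁻¹, floored at 0) and κ log-uniform on [1.0, 5.2]. The BEP
  relation is a modeling convenience for tests, not a claim about any
  specific compound. The "lowest barrier ⇒ largest Γ" pipeline property
  is only guaranteed at equal κ (a κ spread up to 5.2 can reorder
  channels whose barriers differ by less than RT·ln 5.2 ≈ 0.98
  kcal mol⁻¹), so that property test pins κ = 1.
* **Plates** — OD readings back-computed from a 4PL scavenging curve
  around a fixed control absorbance of 0.8, with additive Gaussian noise
  in SP points (default sd 2, n = 3 replicates, default ladder
  8/32/128/265 µg mL⁻¹) and ODs floored at 0. Recovery performance is
  measured over 100 seeded plates on an 8-point two-fold ladder (median
  relative EC50 error < 5% at sd 2).
* **Geometries** — isotropic Gaussian Cartesian perturbations of a base
  structure.

What the simulations do not emulate: correlated plate noise (edge
effects, drift), compound-specific κ/σ structure, non-4PL dose–response
shapes, and anisotropic thermal motion in geometries. Passing tests
demonstrate the pipeline's arithmetic and statistical behavior under
these idealized conditions, not assay- or chemistry-level accuracy on
real data.

## Problem sizes and determinism

The bundled channel tables (27 + 3 channels), 100-plate recovery studies
and 10⁴-channel screening calibration run in seconds on one CPU. All
stochastic tests are seeded (hypothesis runs derandomized); the
acceptance script's reported quantities are deterministic but it accepts
a seed for uniformity.

## Known limitations

* SET kinetics (Marcus theory) intentionally unimplemented — no
  reorganization-energy input exists in the channel contract.
* Variational TST and multidimensional tunneling are out of scope; the
  Eckart model is the most detailed tunneling treatment offered.
* No pH/speciation weighting, ionic-strength or cage-escape corrections.
* The two reference-table inconsistencies found while validating (one
  gas-phase rate row irreproducible from its own printed inputs beyond
  the rounding band; apparent-rate rows implying an encounter rate below
  the Stokes–Einstein floor) are surfaced by the tests rather than
  patched in the fixtures.
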