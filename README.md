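# radscav

Computational evaluation of radical-scavenging (antioxidant) activity:
thermodynamic screening of candidate reaction channels, transition-state
theory kinetics with tunneling and diffusion corrections, branching ratios
and overall rate constants, DPPH dose–response (EC50) analysis, and
internal-coordinate comparison of molecular geometries.

It is aimed at computational/medicinal chemists who have per-site reaction
energetics for an antioxidant candidate (e.g. from DFT thermochemistry) and
want the downstream kinetic and assay arithmetic done reproducibly. The
package ships the complete channel tables and DPPH plate data for ethyl
1,2-diphenyl-1H-pyrrolo[2,3-b]quinoxaline-3-carboxylate ("3a") reacting
with HO•/HOO• radicals, so every stage can be exercised out of the box;
electronic-structure energies are always treated as inputs, never computed.

## Model

A channel is one reactive site paired with one mechanism — formal hydrogen
transfer (FHT), radical adduct formation (RAF) or single electron transfer
(SET). The pipeline:

1. **Screening** — a channel is viable iff its reaction free energy is
   spontaneous, ΔG° < 0 (strict). SET channels are handled at this level only.
2. **TST kinetics** — per viable channel,
   k = σ·κ·(k_B T/h)·exp(−ΔG‡/RT),
   with σ the reaction-path degeneracy and κ a tunneling coefficient:
   supplied as data, or computed by the Wigner model
   (κ = 1 + u²/24, u = hcν‡/k_B T) or from an asymmetric Eckart barrier
   (Boltzmann-averaged transmission probability determined by V_f, V_r, ν‡).
3. **Diffusion correction** (solution phase) — Stokes–Einstein diffusion
   coefficients D = k_B T/(6πηr), Smoluchowski encounter rate
   k_D = 4π·R_AB·(D_A + D_B)·N_A, and the Collins–Kimball apparent rate
   k_app = k_D·k_act/(k_D + k_act). In gas phase k_app = k_act exactly.
4. **Aggregation** — overall rate constant k_overall = Σᵢ k_app,i and
   branching ratios Γᵢ = 100·k_app,i/k_overall.
5. **DPPH assay** — scavenging percentage SP% = 100·(OD₀ − OD₁)/OD₀ at
   517 nm; EC50 from a four-parameter logistic fit (bottom fixed at 0,
   top ≤ 100), censored as "> C" when the response never reaches 50%.
6. **Geometry** — bond lengths/angles/dihedrals, least-squares mean-plane
   r.m.s. deviations, inter-plane angles, hydrogen-bond geometry, and
   crystal-vs-optimized comparison on internal coordinates (no
   superposition, hence rigid-motion invariant).

## Worked example

```python
import radscav as rs
from radscav import datasets

channels = datasets.hydroxyl_channels()          # 3a + HO•: 27 channels
outcomes = rs.screen_channels(channels)
viable = [c for c in rs.viable_channels(outcomes) if c.delta_g_act is not None]
results = rs.branching_ratios(
    rs.evaluate_channels(viable, datasets.gas_conditions()))
print(f"k_overall (gas) = {rs.overall_rate(results):.2e} M^-1 s^-1")
for r in sorted(results, key=lambda r: -r.gamma)[:3]:
    print(f"  {r.site_label:6s} {r.mechanism.value}  k = {r.k_app:.2e}  Gamma = {r.gamma:.1f}%")
```

prints

```
k_overall (gas) = 2.72e+11 M^-1 s^-1
  C12    RAF  k = 1.54e+11  Gamma = 56.5%
  C13    RAF  k = 7.16e+10  Gamma = 26.3%
  C23-H  FHT  k = 4.60e+10  Gamma = 16.9%
```

i.e. 23 of the 27 HO• channels are spontaneous (C4, C9, N3 and SET are
excluded), and the overall gas-phase rate constant of ~2.7×10¹¹ M⁻¹ s⁻¹ is
dominated by radical addition at C12/C13 plus H-abstraction from C23-H —
each k rebuilt here from its (ΔG‡, κ, σ) entry to within the rounding of
the tabulated barriers. The same pipeline with
`datasets.pentyl_ethanoate_conditions()` applies the diffusion correction
in the lipid-mimetic solvent, and

```python
fit = rs.fit_dose_response(datasets.dpph_plates()["3a"], report_threshold=128)
print("3a EC50:", fit.label)        # -> 3a EC50: > 128   (ug/mL, censored)
```

reproduces the censored DPPH result for the lead compound (its scavenging
tops out near 30%, below the 50% needed for a numeric EC50).

The same functionality is available from the shell:

```sh
radscav kinetics --channels channels.csv --conditions gas.yaml --out rates.json
radscav assay --plate plate.csv --censor-threshold 128 --out fit.json
radscav simulate channels --seed 7 --out synthetic.csv
```

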