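# permeapoly

Gas-transport screening for dense polymer membranes: Widom-insertion
solubility, Einstein-relation diffusivity, X-ray structure factors, and
pressure-decay sorption reduction, assembled into solution-diffusion
performance.

## Who this is for

Researchers screening polymer membranes for gas separation (e.g.
CO₂/CH₄ in biopolyesters such as PHBV, random copolymers of
3-hydroxybutyrate and 3-hydroxyvalerate) who work with both molecular
trajectories and pressure-decay sorption experiments and need the two
reduced to the same coefficients:

- **S** — Henry-law solubility coefficient, mol kg⁻¹ bar⁻¹,
- **D** — penetrant self-diffusivity, cm² s⁻¹,
- **P = D·S** and the selectivity factorisation **α = α^D · α^S**.

The package covers the full loop: build random-copolymer particle boxes,
evaluate nonbonded energies and the Hildebrand parameter δ = √(E_coh/V),
estimate μ_ex by Widom test-particle insertion and convert to S via
S = (ρRT)⁻¹ exp(−μ_ex/RT), extract D from multi-time-origin mean-square
displacements (D = lim slope/6), characterise structure through g(r) and
the X-ray-weighted static structure factor S(q), compute probe-insertion
fractional free volume and accessible surface area, and fit
pressure-decay traces with Fickian slab (Crank) kinetics — including the
finite-reservoir solution with decaying interfacial concentration — plus
the two-phase crystallinity correction S_am = S_sc/(1 − X_c).

Every stochastic estimator is seeded and ships with a synthetic-data
generator of known ground truth; see `docs/methods.md` for the models,
assumptions and numerical choices.

## Worked example

Reduce two synthetic pressure-decay experiments (19 µm film, 35 °C,
known ground truth S, D) and assemble the membrane performance:

```python
from permeapoly import (Isotherm, assemble_performance, fickian_d_fit,
                        henry_fit, scale_to_amorphous, step_uptake)
from permeapoly.synthetic import synthetic_pressure_decay

results = {}
for gas, (s_true, d_true) in {"CO2": (0.050, 6.0e-9),
                              "CH4": (0.010, 1.0e-8)}.items():
    step = synthetic_pressure_decay(
        s_true=s_true, d_true=d_true, thickness_um=19.0,
        cell_volume_cm3=10.0, temperature_K=308.15, p0_bar=1.0,
        sample_mass_g=2.0, noise_sd_bar=0.002, seed=1, gas=gas)
    n = step_uptake(step)                       # moles absorbed vs time
    c_eq = n[-1] / (step.sample_mass_g * 1e-3)  # mol/kg at equilibrium
    S = henry_fit(Isotherm([step.p_final], [c_eq])).S_mol_kg_bar
    D, se = fickian_d_fit(step, noise_band_bar=0.002)
    results[gas] = (S, D)
    print(f"{gas}: S = {S:.4f} mol/kg/bar   D = {D:.3e} cm2/s")

rec = assemble_performance(*results["CO2"], *results["CH4"], "CO2", "CH4")
print(f"alpha_S = {rec.alpha_S:.2f}  alpha_D = {rec.alpha_D:.2f}  "
      f"alpha = {rec.alpha:.2f}")
print(f"amorphous-basis S_CO2 (X_c = 0.42): "
      f"{scale_to_amorphous(results['CO2'][0], 0.42):.4f} mol/kg/bar")
```

Output:

```
CO2: S = 0.0497 mol/kg/bar   D = 6.028e-09 cm2/s
CH4: S = 0.0098 mol/kg/bar   D = 1.017e-08 cm2/s
alpha_S = 5.09  alpha_D = 0.59  alpha = 3.01
amorphous-basis S_CO2 (X_c = 0.42): 0.0856 mol/kg/bar
```

The fitted coefficients recover the generator's ground truth within the
pressure noise (S within 1%, D within 3%); the solubility-selectivity
(≈5) dominating a sub-unity diffusivity-selectivity (≈0.6) is the
signature of a sorption-driven CO₂-selective membrane. The 2%-noiseless
/ 3σ-noisy recovery guarantees are enforced by the test suite.

## Command line

A thin CLI wraps the library:

```bash
permeapoly build --n-chains 5 --chain-length 150 --x-hv 0.08 \
    --density 1.17 --seed 1 --out box.pdb
permeapoly widom --traj box.pdb --params ff.yaml --gas co2 \
    --n 1000000 --temp 308 --seed 7 --json widom.json
permeapoly msd --traj nve.dump --dt-ps 0.5 --max-lag 5000 --out msd.csv
permeapoly sorption-fit --steps step1.csv --meta meta.yaml
permeapoly {fixtures, energy, rdf, sq, ffv, asa, report} --help
```

All commands echo their seed and parameters into the output files.

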