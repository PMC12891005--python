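# myconet

Quantifying reciprocal carbon–phosphorus exchange in arbuscular mycorrhizal
(AM) fungal networks from network morphology, and modelling the growth
strategies that a fixed exchange rate permits.

AM fungi trade soil phosphorus for plant carbon. Both sides of that trade
can be estimated from hyphal morphology alone: the carbon a network costs
its host scales with its total cell **volume** (`V = Σ π r_i² L_i` over
edges, plus spore spheres `4/3 π r_k³`), while the phosphorus it can absorb
scales with its membrane **surface area** (`S = Σ 2π r_i L_i`), because
uptake is limited by membrane transporters at a characteristic areal
density. `myconet` implements that estimation pipeline and the growth
theory built on it:

- **morphometry** — totals (L, S, V), convex-hull area A, wave radius
  `R_wave = √(A/π)`, densities ρ, ρ_S, ρ_C and the range-expansion speed
  `v_wave` from spatial-graph snapshots of the mycelium;
- **radius_estimator** — a regressor mapping 120-sample intensity
  transects to hyphal radius (hyphae are sub-resolution at plate-scanner
  magnification), with grouped 90/10 splitting and 20-bin test resampling;
- **exchange_fluxes** — carbon content `C_t = M_C (ΣV_i + ΣV_k)` and
  expenditure `Φ_C = (dC_t/dt)/CUE`; transporter-limited P uptake
  `dP_f/dt = −J([P])·S` with Michaelis–Menten `J([P]) = J_max [P]/([P]+K_m)`,
  calibrated from depletion assays (J = −slope of P_f against ∫S dt) and
  integrated self-consistently into the supply rate `Φ_P = J([P])·S`;
  media-P accounting for the culture-plate recipe; through-origin
  exchange-rate fits `κ = Φ_C/Φ_P` and binned averages;
- **wave_model** — a radial branching/anastomosis traveling-wave PDE
  (`∂ρ/∂t = v_g n`, `∂n/∂t = αn − βnρ − ∇·j(n)`) coupled to the P field,
  extended with a negative integral feedback `dα/dt = F(κ)` that holds the
  exchange ratio at a setpoint κ₀, and a speed-dependent hyphal radius
  `⟨r⟩ = a·v_wave + b`;
- **pareto_analysis** — the family of isoexchange curves
  `ρ_S(v_wave) = κ₀·CUE·[P]₀·d / (M_C π ξ (a·v_wave + b))` bounding
  achievable (speed, density) strategies at fixed κ₀, empirical
  moving-maximum fronts, and a strategy × environment sweep of total P
  capture;
- **synthetic_data** — a generator for all pipeline inputs (traveling-wave
  network timelapses, depletion assay tables, transect datasets) with
  known ground truth, so every stage is testable end to end;
- **pipeline / CLI** — a `myconet` command with per-stage verbs and a
  manifest-tracked `run` orchestrator.

## Worked example

```python
import numpy as np
import myconet as m

media = m.media_phosphorus()          # the high-P culture-plate recipe
config = m.SyntheticRunConfig(seed=1, duration_h=200.0)
timelapse = m.generate_timelapse(config)

series = m.compute_series(timelapse.snapshots)
v_wave, diag = m.wave_speed(series, window_h=100.0)

assay = m.generate_depletion_assay(config, 3.0, np.linspace(25, 200, 8))
cal = m.calibrate_J(assay, seed=1)

result = m.run_simulation(m.default_params(150.0, Rmax_mm=200.0), 900.0)
late = result.saves[result.saves.t_h > 300.0]
slope, ci = m.exchange_ratio_fit(late.PhiC_ug_per_h, late.PhiP_ug_per_h, seed=1)
```

prints, step by step:

```
compartment P: 96.4 ug total (3.44 ug/mL), accessible 1.44 ug/mL
wave speed: 150.4 um/h (R^2 = 1.0000)
calibrated J: 2.93 ng/mm^2/h (95% CI 2.26-3.42, R^2 = 0.81)
simulated exchange rate: kappa = 2.96 mass C per mass P (setpoint 3.0); realised v_wave = 143 um/h
```

Reading the numbers: the 28-mL fungal compartment holds 96 µg of
phosphorus, of which 1.44 µg/mL is actually accessible once the adsorbed
baseline (2 µg/mL) is subtracted. The synthetic colony expands as a
traveling wave at its configured 150 µm/h. Regressing the remaining
compartment P against the time-integrated network surface area recovers
the areal uptake coefficient J near its generating value of
3 ng·mm⁻²·h⁻¹ — the same coefficient that implies a 1-m network of 3-µm
hyphae extracts about 1 µg of P per day. Finally, the extended
traveling-wave model with integral feedback holds the realised
carbon-per-phosphorus exchange ratio at the configured setpoint of 3.

The same steps are available from the shell:

```sh
myconet generate --kind timelapse --seed 1 --out runs/tl
myconet morphometry --in runs/tl --out runs/series.csv
myconet generate --kind assay --seed 1 --out runs
myconet calibrate-j --assay runs/assay.csv
myconet simulate --v-wave 150 --t 900 --out runs/sim.csv
myconet pareto --mode curve --out runs/curves.csv
```

## Further reading

`docs/methods.md` documents the model assumptions, parameter defaults
(with units and rationale), the numerical scheme, what the synthetic data
do and do not emulate, and known limitations.
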