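# Methods

This note documents the models, parameter choices and numerics behind
`myconet`, in the order the pipeline runs.

## 1. Morphology-based flux estimation

**Assumptions.** Hyphal segments are cylinders (radius r, length L) and
spores are spheres; the network is effectively two-dimensional on the gel
surface; during steady-state traveling-wave expansion the cell composition
is constant, so carbon content is proportional to cell volume with a fixed
conversion `M_C = d_cell · f_dry · f_carbon`.

Carbon content is `C_t = M_C (Σ_edges π r_i² L_i + Σ_spores 4/3 π r_k³)`
and the expenditure rate is `Φ_C = (dC_t/dt)/CUE`, a leading-order growth
cost: maintenance respiration (∝ C_t) and CUE variation are neglected.
Negative finite-difference derivatives of `C_t` are floored at zero and
flagged — standing biomass is not un-built at this order, so negative
increments are measurement noise.

Phosphorus uptake is transporter-limited: `dP_f/dt = −J([P])·S` with
`J([P]) = J_max [P]/([P] + K_m)`. While transporters are saturated this
integrates to the calibration line `P_f(t_m) = P_f(0) − J ∫₀^{t_m} S dt`,
so J is recovered as minus the slope of compartment P against the
time-integrated surface area (ordinary least squares; percentile bootstrap
over assay rows for the CI). The supply rate `Φ_P = J([P])·S` is then
integrated with a *well-mixed accessible-pool* correction: the accessible
concentration `[P](t) = (budget − cumulative transfer)/V_gel` feeds back
into `J([P])`, so uptake slows and stops as the pool empties. The update
is explicit with ≤ 0.25-h substeps; against a high-accuracy ODE solution
of the same law the cumulative transfer agrees to < 0.1% at 2-h sampling.

**Media-P accounting.** Compartment P = KH₂PO₄ contribution (P mass
fraction 0.2276 from standard atomic masses) + gelling-agent contribution
(27 µmol P per g of Phytagel). An adsorbed baseline of 2 µg/mL is
inaccessible to both partners; accessible concentration = total − 2,
floored at zero. The caption value of 0.6 µg/mL sometimes quoted for the
low-P accessible concentration conflicts with the recipe arithmetic
(0.5 µg/mL); the arithmetic value is used.

**Carbon constants.** `d_cell = 1.1 g/cm³`, `f_dry = 0.25`,
`f_carbon = 0.45` (so `M_C ≈ 124 µg/mm³`) and `CUE = 0.5` are documented
placeholders: M_C for AM fungi has not been measured directly, and CUE is
a soil-fungus average with ~30% relative uncertainty. Both enter all
carbon fluxes multiplicatively, so exchange-rate ratios rescale simply if
better values become available; every result carries them via
`CarbonParams`.

## 2. Radius estimation from transects

At plate-scanner magnification a 1–7-µm hypha spans only a few pixels, so
the radius is regressed from the full 120-sample perpendicular intensity
profile rather than a thresholded width. Protocol: (i) group-aware 90/10
train/test split — all transects from one acquisition source stay on one
side, making the test set independent; (ii) the test set is resampled with
replacement to the training labels' 20-bin frequency distribution (bins
with training mass but no test members are skipped with a warning);
(iii) the regressor operates on background-normalised absorbance
(`1 − I/background`, background from the outer 20 px per side), which
removes illumination scale; (iv) evaluation by RMSE (µm) and R².

The default regressor is a multilayer perceptron (64/32 hidden units)
fitted with L-BFGS — full-batch and therefore deterministic under seed and
invariant to training-row order; gradient-boosted-tree and ridge
regressors sit behind the same interface. Network application takes the
median over per-10-px-segment transect predictions along each edge,
excluding transects predicted below 0.3 µm as empty background;
predictions are clamped at zero.

A manual-measurement noise of SD 0.3 µm on the labels sets an irreducible
RMSE floor; the test suite checks both the clean-signal round trip
(< 0.2 µm) and that the reported RMSE respects the floor in the noisy
regime. Printed test metrics from real imaging datasets are properties of
those datasets and are not reproduction targets here.

## 3. Extended traveling-wave model

Radially symmetric fields on `R ∈ [0, R_max]`: hyphal length density
ρ(R,t) (µm/mm²), tip density n(R,t) (mm⁻²) and accessible P concentration
[P](R,t) (µg/mL) in a gel of depth d:

    ∂ρ/∂t = v_g n
    ∂n/∂t = α n − β n ρ − ∇·j(n),   j(n) = c n − D ∇n
    ∂[P]/∂t = −J([P]) · ρ_S / d,     ρ_S = 2π⟨r⟩ρ

with `⟨r⟩ = a·v_wave + b` (thicker hyphae in faster strategies) and
`⟨r²⟩ = ξ⟨r⟩²`, ξ = 1 + CV² of the radius distribution. Carbon
expenditure is the building term `(M_C/CUE)·π⟨r²⟩·v_g·∫n dA` plus a
spore-production term `σ_spore·∫ρ dA` proportional to standing mycelium;
P supply is `Φ_P = ∫ J([P]) ρ_S dA`.

**Flux law j(n).** The advection + diffusion form is a minimal flux law
supporting constant-speed fronts. The front is pulled (speed
≈ `c + 2√(D_eff α)` with `D_eff` including the upwind scheme's numerical
diffusion), so `default_params` calibrates c against that dispersion
relation to land near a nominal target speed; the realised speed is always
measured from the run by fitting the front position, never assumed.

**Exchange-rate feedback.** The branching rate carries a negative integral
feedback holding κ = Φ_C/Φ_P at the setpoint κ₀. It is implemented on the
logarithm, `d ln α/dt = −k_I (κ − κ₀)/κ₀`: before a depleted zone exists,
κ is structurally independent of α (the density cancels from Φ_C/Φ_P in
the pure traveling-wave regime), and an additive law integrating that
uncontrollable error drives α into its zero clamp, killing the wave
irrecoverably. The multiplicative form keeps α positive and the loop gain
scale-free. For the same reason the integral *engages* only once the
depletion annulus detaches from the colony front (ΔR < 0.8 R_front) —
before that the loop has no control authority. κ is smoothed with a 6-h
exponential window before entering the controller, and the feedback is
inactive while Φ_P is negligible. α is clamped to [0, α_max].

**Spore carbon coefficient.** With the spore term proportional to total
standing mycelium, its share of Φ_C grows roughly linearly in colony
radius. Anchoring a ~25% share at 100 h would let spore carbon dominate a
multi-hundred-hour run, leaving no steady exchange ratio for the
controller to hold; the default `σ_spore = 5×10⁻⁹ µg/(µm·h)` instead puts
the ~25% share near the end of the 900-h default horizon, subdominant
early. Experimentally reported spore shares refer to ~100-h-old real
networks; treat absolute spore-carbon fractions from this model as
qualitative.

**Regime structure and cross-checks.** The model reproduces the three
analytic regimes: exponential establishment; the traveling-wave regime
where (without spore carbon) `Φ_C/Φ_P ∝ 1/R_wave` (measured log-log slope
−1.0 ± 0.1); and the depletion regime, where the P-depletion front
co-moves with the growth front, ΔR stabilises, and the ratio converges to
the closed form `κ = ρ_C/(CUE·[P]₀·d)` (within 10% in the tests; the
regime boundaries t₀ and t₁ are detected from the front-position fit and
ΔR stabilisation respectively). The annulus formula
`Φ_P = J·2π·ρ_S·R_wave·ΔR` matches the simulated supply when ΔR is taken
as the *uptake-equivalent* width `∫ J([P]) dR / J([P]₀)` and ρ_S as the
J-weighted annulus density — with a Michaelis–Menten ramp the sharp-front
ΔR of the idealised formula has no unique threshold definition, and the
uptake-equivalent width is the operational one. Both definitions are
available in `depletion_width`.

**Numerics.** Explicit Euler; conservative cylindrical finite volumes;
first-order upwind advection and centred diffusion; reflective boundary at
R = 0; outflow at R_max ("open") or a reflective dish wall ("closed").
Defaults ΔR = 0.25 mm, Δt = 0.25 h, D = 0.04 mm²/h; with physical
diffusion dominating the scheme's numerical diffusion, halving ΔR and Δt
moves the fitted wave speed by < 2%. CFL conditions are validated at
construction; field blow-up raises an error naming the violated margins.
Branching is cut off below a tiny tip density (10⁻⁴ mm⁻²) so the leading
edge cannot amplify arbitrarily small densities. P removal per step is
capped at the locally available P, making the discrete balance — field
deficit × gel volume = cumulative transferred P — exact to rounding.
Per-step P bookkeeping, positivity of all fields and the budget cap are
asserted in the test suite.

**Initial condition.** A Gaussian tip pulse at the origin (SD 1 mm), bare
substrate (ρ = 0), uniform [P] = [P]₀.

## 4. Pareto analysis and the strategy sweep

In the depletion regime, fixing κ₀ fixes the carbon density
`ρ_C = κ₀·CUE·[P]₀·d`; with the speed–radius law this yields the
isoexchange family `ρ_S(v_wave) = κ₀·CUE·[P]₀·d/(M_C π ξ (a·v_wave + b))`
— decreasing and convex in v_wave, ordered and linear in κ₀. The curve is
stated up to a convention-dependent constant factor (substituting the
closed-form κ directly into ρ_S = 2π⟨r⟩ρ gives the same shape with a
different prefactor); all structural properties are invariant to that
factor. The gel depth d is kept explicit. The empirical front is the
running maximum of ρ_S in order of decreasing v_wave, with no smoothing.

The strategy sweep evaluates total P capture over a `v_wave × [P]₀` grid.
A *strategy* is a heritable phenotype on the isoexchange front of a
reference environment (accessible 1.4 µg/mL): its nominal speed sets its
hyphal radius, and its initial branching rate is chosen so the colony
density matches the isoexchange relation at that speed — slower strategies
are denser. Each cell runs the full feedback model in a closed 40-mm dish
to 900 h; rows are normalised by their mean. Two regimes emerge: in
P-poor substrate the local pool exhausts quickly and capture is
covering-limited, favouring fast expansion that escapes the
self-generated depletion zone; in P-rich substrate capture is
surface-(rate-)limited over the whole horizon, favouring slow, dense
strategies. The default rows (0.35–60 µg/mL) span that transition; the
upper rows exceed plate-culture concentrations and represent P-rich
environments generally. Without trait densities the rich-substrate
ordering inverts (thicker fast hyphae win on raw surface area), which is
why the sweep fixes strategies on the reference front rather than letting
each cell re-adapt its density to its own environment.

## 5. Synthetic data: what it emulates, and what it does not

The generator realises the study conditions: 2-h sampling over a < 200-h
steady-state window; a colony expanding at constant speed (default
150 µm/h) and constant length density behind the front (default
300 µm/mm²); a two-mode lognormal radius mixture (thin absorbing-structure
mode, median 1.5 µm; thick runner mode, median 3 µm) spanning the observed
1–7 µm; runners widening at 0.015 µm/h (3 → 4.5 µm over 100 h); spores
appearing behind the front; assay tables with surface-proportional
depletion, constant gel baseline and mass closure plus additive Gaussian
noise (SD 0.5 µg); transects from a Beer–Lambert cylinder-projection model
with defocus blur (±0.1–0.2 mm), ±20% illumination scale, additive
intensity noise and 0.3-µm label noise, grouped into acquisition sources.

Networks are realised as radial *wedge* edge populations — per-edge
(r, L) with approximate planar placement — not as connected 2-D
skeletons: every downstream statistic uses only per-edge geometry and the
hull of node positions, so skeleton topology is out of scope. Spore
placement is uniform behind the front with lognormal radii (median 25 µm);
no published spatial law exists, so these are documented choices. Noise is
additive Gaussian throughout. Consequently, passing tests demonstrate
correctness of the estimators *given* the stated generative structure;
they do not validate segmentation, skeletonization, or robustness to
imaging artifacts beyond the modelled defocus/illumination/noise terms.

## 6. Problem sizes used in tests and the acceptance script

Round-trip tests use 100–200-h timelapses (1,500–3,000 edges), transect
datasets of 1,500–2,000 samples, 200 simulated assays for bootstrap
coverage, 900-h model runs on 600–800-cell radial grids, and a 4 × 4
strategy sweep in a 40-mm dish. These sizes give sub-percent Monte-Carlo
error on every asserted quantity while keeping the full suite fast.

## 7. Known limitations

- M_C and CUE are literature placeholders; absolute carbon fluxes (and
  therefore the absolute exchange rate) inherit their uncertainty, while
  ratios between conditions do not.
- The well-mixed accessible-pool correction ignores spatial P gradients in
  the flux-estimation path (the wave model resolves them radially).
- The flux law j(n) is a minimal substitute for tip-scale transport
  statistics; realised speeds are measured, and conclusions that depend
  only on the existence of constant-speed fronts are insensitive to its
  exact form.
- The spore-carbon term is proportional to standing mycelium; real spore
  production saturates and localises, so late-time spore fractions are
  qualitative.
- The sweep's strategy definition (traits frozen on a reference-front) is
  one defensible reading of a strategy/environment decomposition; a
  fully plastic alternative (per-environment re-adaptation) erases the
  rich-substrate advantage of dense strategies.
- The feedback engagement rule (depletion-front detachment) is a modelling
  device for control authority, not a measured biological switch.
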