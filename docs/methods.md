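# Methods

## Stomatal optimality model

Stomata are modelled as minimising water lost per unit carbon gained,
using the closed-form unified approximation

    gs = 1.6 (1 + g1 / D^k) · A / Ca

with D the leaf-to-air VPD (kPa), A net assimilation (µmol m⁻² s⁻¹), Ca
the CO₂ mole fraction at the leaf (µmol mol⁻¹) and gs the stomatal
conductance to water vapour (mol m⁻² s⁻¹). The slope g1 is recovered per
observation by the algebraic inversion

    g1 = (Ci/Ca) · D^k / (1 − Ci/Ca),

which makes `predict ∘ estimate` collapse exactly to the diffusion
identity `gs = 1.6 A/(Ca − Ci)`; the package asserts this to 1 × 10⁻¹²
and uses it as its principal self-check.

Design choices where the procedure was genuinely open:

- **g1 aggregation.** Per-observation g1 values are aggregated by the
  *median* (default): porometry at low Ci produces heavy-tailed outliers
  that a mean would chase. Mean and origin-regression aggregation are
  available (`g1_method`).
- **VPD exponent.** The classic model fixes k = 0.5. Here k is selected
  from the candidate set {0.2, 0.5, 0.8} (arbitrary k ∈ (0, 1] is
  accepted) by RMSE of predicted vs observed gs. g1 carries units kPa^k,
  so fits at different k are compared only through RMSE/R², never through
  g1 magnitude.
- **Selection metric.** RMSE, with R² reported alongside; on noise-free
  model-generated data the true exponent attains RMSE = 0 exactly.

VPD itself is computed with the Tetens saturation-vapour-pressure form
es = 0.61078·exp(17.27 T/(T + 237.3)) kPa, chosen because it reproduces
both nominal canopy regimes to two decimals (27 °C/60 % RH → 1.43 kPa;
37 °C/50 % RH → 3.14 kPa); the constant triple is swappable.

## FvCB photosynthesis model

Net assimilation is the hard minimum of the rubisco-limited and
RuBP-regeneration-limited rates,

    Ac = Vcmax (Ci − Γ*) / (Ci + Kc(1 + O/Ko))
    Aj = Jmax (Ci − Γ*) / (4 Ci + 8 Γ*)
    A  = min(Ac, Aj) − Rd.

The hard minimum (rather than a hyperbolic smoothed minimum, available via
`smoothing`) keeps per-point limitation labels unambiguous. TPU limitation
is excluded by default; mesophyll conductance is assumed infinite (fitting
is on a Ci basis).

Kinetic constants default to the Bernacchi tobacco determination at 25 °C
(Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, Γ* = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹) as a named, swappable set. Temperature scaling uses
Arrhenius responses with activation energies (kJ mol⁻¹) Kc 79.43,
Ko 36.38, Γ* 37.83, Vcmax 65.33, Rd 46.39, and a peaked Arrhenius for
Jmax (Ea 43.54, Hd 200, ΔS 0.635 kJ mol⁻¹ K⁻¹), so curves measured at
27 °C and 37 °C are comparable on a common 25 °C basis.

Fitting is deterministic: initial Vcmax from the low-Ci (< 250 µmol mol⁻¹)
linearisation of the rubisco branch, initial Jmax from the highest-Ci
point, then Levenberg–Marquardt least squares (lmfit) over
(Vcmax, Jmax, Rd). Curves with fewer than three points below the
inflection raise a "vcmax weakly constrained" warning; non-convergence
raises an error carrying the best-so-far parameters. The fit is invariant
to point order and to the duplicated recovery steps that the standard
19-step CO₂-reference sequences contain.

The supply-function operating point solves
`A_FvCB(Ci) = (Ca − Ci) · gsw/1.6` by Brent bisection on [Γ*, Ca]
(xtol 10⁻¹⁰); relative stomatal limitation is
`l = (A(Ci=Ca) − A*)/A(Ci=Ca)`. No sign change over the bracket (e.g.
respiration exceeding gross assimilation throughout) returns a
degenerate-supply flag rather than an answer.

## Surface partitioning and thermal offsets

Whole-leaf fluxes are arithmetic sums of the two surfaces; the abaxial
percentage share is 100·ab/(ab+ad), computed independently for E and gsw
(the headline partitioning uses E). Shares are variance-stabilised with
asin(√p); negative single-surface porometer readings cannot be
transformed, so they are *flagged at ingest and excluded explicitly* by
the transform, never silently dropped. Flux–ΔT regressions (ΔT = leaf
minus dry-reference temperature, negative = cooler leaf) are fitted on
treatment means — one point per factorial cell — with order 1 for E and
order 3 for gsw; raw-record regression sits behind a flag. ΔT is treated
purely as a relative cooling index; no energy-balance inversion is
attempted.

## Kinetics

Light-shift traces follow the fixed phase plan steady (0–5 min) → dark
(5–65 min) → relight (65–125 min). Initial closing/opening rates are OLS
slopes of gsw on time over the first 20 min of each shift — OLS is
noise-robust and reduces exactly to the two-point difference for linear
traces; a `two_point` mode is provided. Endpoint conductances use the
nearest sample within 1 min of 65 and 125 min, which makes the summary
invariant to sub-half-minute sampling jitter; a > 5 min gap inside an
analysis window is a coverage error. Percentage dark closure is
100·(g0 − g(65))/g0. No induction time-constant (τ) is fitted.

CO₂ blindness is diagnosed from the OLS slope of gsw on the CO₂ reference
concentration over the supra-ambient steps (≥ 4 required):
|slope| < 2 × 10⁻⁵ mol m⁻² s⁻¹ per µmol mol⁻¹ is labelled "blind".
The threshold is a package decision (the phenomenon is qualitative) and
is exposed in config.

## Leaf phenotypes

Stomatal density divides total stomata over the two fields of view by the
total counted area (1.2049 mm²); stomatal size averages five guard-cell
lengths per field, then the two fields. Chlorophyll uses the Wellburn
DMF coefficients (Chl a = 12.00·A663.8 − 3.11·A646.8;
Chl b = 20.78·A646.8 − 4.88·A663.8; carotenoids from A480 when measured),
scaled by extract volume; dry-mass normalisation multiplies the disc
fresh mass by a dw/fw ratio and reports µg chlorophyll per mg estimated
dry mass with the intermediate quantities attached, because "content by
mass" units are ambiguous in common practice — outputs carry explicit
units rather than a guessed axis. MTCI extracts the 754/709/681-nm bands
by linear interpolation on the measured grid (nearest-band optional; at
1-nm resolution the two coincide) and flags a near-zero red-edge
denominator as undefined. Whole-cycle WUE is ear mass over water applied;
its reciprocal (ml g⁻¹) satisfies wue · ml_per_g = 1000 exactly.

## Synthetic-data generator

The generator is the study-design forward model, not a fixture file: all
randomness flows from one integer seed through `numpy.random.default_rng`,
with an independent child stream per stage so stages can be re-run in any
order. Defaults encode the factorial conditions — 2 CO₂ (450/720 ppm) ×
2 VPD regimes × 4 N levels × 32 plants; a 16/16 watered/drought split; the
two 19-step CO₂-reference sequences; 5/60/60-min light-shift phases; a
12-day drought sampled every 3 days; a 148-day season — and a qualitative
effect pattern: g1 of 2.5 (ambient) vs 5.0 (heatwave) kPa^0.8 with a 0.7
multiplier for elevated CO₂ under ambient VPD only; Vcmax at 25 °C rising
from 60 to 95 µmol m⁻² s⁻¹ across N1–N4 (Jmax = 1.8·Vcmax); abaxial flux
shares of 0.09 (ambient) vs 0.45 (heatwave); dark-closure fractions of
0.80 vs 0.375; drought E half-lives of 6 vs 3 days; season water totals of
12.6/6.09 l (ambient regime, 450/720 ppm) and ~13 l under heatwave.
Steady-state output is exactly Eqn-consistent: Ci/Ca = g1/(g1 + D^k), A
from FvCB at that Ci, gs from the optimality form, E = gs·D/P·1000 —
so with noise standard deviations set to zero the fitting routines must
(and do) recover the configured parameters to machine precision. Gaussian
noise (default 5 % relative on gsw, 0.5 µmol m⁻² s⁻¹ on A/Ci assimilation,
0.002 mol m⁻² s⁻¹ on kinetics traces) is layered on top.

What the generator does **not** emulate — and hence what passing tests do
not show about real leaves: A–gsw decoupling beyond the optimality
closure, boundary-layer and within-canopy microclimate gradients,
instrument drift and matching errors, diurnal nonstationarity, or any
soil-water mechanism (drought is a prescribed exponential decay).
Generator-recovery checks are self-consistency statements about the
forward model, never reproductions of measured plant values.

## Problem sizes

Default test and acceptance runs use the full factorial (1024 steady-state
surface records), 16 A/Ci curves, 16 kinetics traces, 10⁴ identity draws,
50 noisy A/Ci recovery curves and 100 supply-oracle parameter sets; the
whole suite completes in a few seconds on one core.

## Known limitations

- The optimality fit assumes saturating-light steady state; no marginal
  water-cost (λ) derivation is attempted beyond the closed form.
- A/Ci fitting has no chlorophyll-fluorescence constraint on J and no
  mesophyll-conductance estimation; at strongly limiting light the
  J = Jmax assumption overestimates the RuBP branch.
- Porometer E is taken as exported, with the area basis recorded as a
  dialect note (`area_basis`) but never converted — vendors differ on
  projected vs per-side leaf area.
- Group comparisons are descriptive (mean ± s.e. per factorial cell);
  inferential statistics are left to dedicated tooling.
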