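# Methods

This note documents the models implemented in `pyresed`, their assumptions,
the defaults that matter, and what the synthetic scenario generator does and
does not emulate.

## Field-scale pesticide balance (`field_model`)

The soil column is a stack of compartments with static geometry (thickness,
bulk density, organic-carbon fraction). Per compound, each compartment holds
adsorbed and dissolved mass. The daily sequence is: application deposition →
phase re-equilibration → soil decay → runoff → dissolved extraction →
erosion removal.

**Erosion removal with a soil-interaction depth.** The central algorithm
treats the top D_E of soil (default 1 cm, uniform weighting — both
configurable) as the zone exchanging adsorbed pesticide with eroding
sediment. The eroded-sediment concentration is the return-to-unit weighted
average of compartment concentrations over [0, D_E]; a compartment straddling
D_E is weighted by its intersected thickness. Removal per compartment is
proportional to its contribution w_j·C_s,j and is implemented as a capped
first-order loss: the total equals min(J_ER·dt, adsorbed mass available in
the weighted zone), with shortfall redistributed across non-exhausted
compartments so the cap is exact. The legacy single-compartment behaviour is
retained as `mode="original"` for comparison; the two modes coincide when the
compartment thickness equals D_E. We implement the loss-term contract
(proportional, availability-capped removal), not the tri-diagonal implicit
solver of the full root-zone code whose diagonal the loss term would enter;
at a daily step and the removal fractions encountered here the difference is
below the 1% invariance tolerance the tests enforce.

**Hydrology.** The full root-zone hydrology (crop growth, ET, percolation)
is out of scope; runoff is generated by the SCS curve-number method on daily
precipitation plus a fixed irrigation schedule (default 10 cm every 10 days,
June–September — a furrow-irrigation magnitude that produces the summer
runoff events pyrethroid transport depends on). Percolation between
compartments is omitted: pesticide leaves the column only by decay, runoff
extraction, and erosion. Event soil loss is MUSLE,
X_e = 11.8(Q·q_p)^0.56·K·C·LS·P, with peak flow q_p = daily volume / 86400 s
times a peakedness factor (default 2.0).

**Other field choices.**
- Applications are incorporated uniformly over the top 1 cm (default). This
  depth is defined on the depth axis, not the grid, so discretization
  comparisons are meaningful.
- Dissolved/adsorbed equilibrium is re-established daily from the linear
  isotherm (Kd = Koc·f_oc) at a constant volumetric water content θ = 0.3.
- Runoff extraction weights dissolved concentration by an exponential curve
  over the top 2 cm whose density at 2 cm is 1% of the surface value (the
  curve's constant is not standardized; this choice is exposed as a module
  constant).
- Enrichment ratio r_om defaults to 1.0 (no enrichment); it is a plain
  multiplier when sorbed fines are known to be enriched.
- Erosion removes pesticide mass but not soil geometry; the column does not
  thin. This is the usual root-zone-model simplification and a known
  limitation for extreme cumulative erosion.

## Routing (`routing`)

The flow-path redistribution function U(t) (loss factor K, lag T,
shear/storage Δ) is algebraically the inverse-Gaussian density with mean T
and shape T/(2Δ). Kernels therefore come from exact CDF differences on bins
centered at integer-day lags, subdivided into 48 sub-slices whose midpoints
carry the in-transit decay attenuation exp(−ln2·t/half-life). This is
mass-exact for the undecayed kernel and O((k·h)²) accurate for decay (k the
daily decay rate, h the sub-slice width) — about 10⁻⁵ relative at the
half-lives used here. The horizon auto-extends until 99.95% of the kernel
mass is captured (parameter `mass_capture`). Decay is applied inside the
kernel rather than post hoc per reach; for a pure transit path the two are
equivalent and the kernel form keeps convolution linearity exact.

The pesticide dispersion coefficient is the sum of molecular and flow
diffusivity; Δ scales by (D_flow + D_mol)/D_flow, a negligible correction at
realistic magnitudes (D_mol ≈ 5×10⁻¹⁰ m²/s) but kept for completeness. The
loss factor K is a flat multiplier with no flow dependence.

## Channel (`channel_model`)

Each reach is a continuously stirred tank of fixed water volume over a
well-mixed active sediment layer (default 0.05 m deep, porosity 0.5,
particle density 2.65×10⁶ g/m³ — standard mineral density; bed organic
carbon 1%). Daily order of operations (fixed, because mass splits depend on
it): inflow mixing → peak velocity from the day's inflow → transport
capacity → solid deposition/resuspension → pesticide moving with the solids
→ water/bed diffusion → decay (aquatic half-life in water, sediment
half-life plus optional burial rate in the bed) → outflow at mixed
concentration.

- Transport capacity C_ss,max = SPCON·V^SPEXP with defaults 10⁻⁴ and 1.5
  (mid-range of the sediment-routing convention these coefficients come
  from); resuspension is capacity-deficit-limited per day — the deficit
  times erodibility×cover, never more than the bed holds.
- Diffusion uses two-film Mackay D-values with Z = 1/H for both aqueous
  phases, molecular diffusivity 4.3×10⁻⁵ m²/day on the water side and the
  same value scaled by porosity^(4/3) (Millington–Quirk) on the sediment
  side. The water-side boundary layer is 0.02 m; the sediment-side layer
  follows the empirical power law 318·Kd^0.683 read in meters. The printed
  units of that power law are ambiguous in its source convention; it is
  isolated in `sediment_boundary_layer_m` and overridable per reach so a
  different reading is a one-line change. With the as-printed values the
  sediment-side resistance dominates and diffusive exchange is slow relative
  to particle-bound exchange — consistent with the particle-dominated
  transport the model is built for.
- The daily diffusion update moves J·dt but never past the closed-form
  two-box equilibrium (equal dissolved concentrations), making the explicit
  step unconditionally stable and monotone in the fugacity difference.

## Toxicity (`toxicity`)

TU is additive across compounds. The tabulated LC50s are 10-day *H. azteca*
dry-weight values for sediment containing 1% organic carbon, so the default
basis rescales a sample's dry-weight concentration to the 1%-OC reference
(conc·0.01/f_oc) before dividing; the alternative basis (`per_g_oc`) treats
the tabulated values as ng/g-OC directly. Both conventions circulate in the
sediment-toxicity literature; the switch makes the choice explicit. MDL
censoring (below-limit → 0) is applied before normalization; exact
non-detects are floored at TU = 0.01 for display only. The dose-response
curve is M = 100/(1 + exp(−(a + b·log₁₀TU))) with fixed 0/100 asymptotes and
b ≥ 0, fit by least squares.

## Statistics (`stats`)

- Flow-weighted monthly concentration: Σ(c·q)/Σ(q) per calendar month.
- Pearson r with two-tailed p from t = r√(n−2)/√(1−r²).
- Sequential variance decomposition: share of the first predictor is its
  marginal R², the second gets the joint-R² increment; shares sum to the
  joint R² exactly and are order-dependent by construction. The packaged
  exposure analysis restricts to years with nonzero September–October
  bifenthrin use and uses the November–December precipitation column as the
  precipitation variable; the joint R² computes to 90.1% on the packaged
  table while the two sequential shares round to 54.9% and 35.3% (summing to
  90.2% after rounding).
- "R²" for model evaluation is the squared correlation convention;
  Nash–Sutcliffe efficiency is provided separately because squared
  correlation ignores bias.
- USLE crop-factor calibration is a transparent grid search (deterministic,
  reproducible); ties resolve to the smallest candidate with a warning.

## Synthetic scenario generator (`scenario`)

The generator defines the study conditions the tests run under; it emulates
a Mediterranean-climate agricultural watershed:

- **Weather:** monthly wet-day probabilities and gamma-distributed wet-day
  depths concentrated in November–March, each calendar year rescaled to an
  annual total drawn uniformly from 6.4–47.4 cm. Long-run November–March
  share of precipitation is ≥ 70%.
- **Applications:** monthly mass weights placing 50% of annual use in
  July–August and 70% in June–September, with a configurable September–
  October share (default 0.1) emulating late-season bifenthrin timing.
  Default annual watershed totals: bifenthrin 30, λ-cyhalothrin 60,
  esfenvalerate 40, permethrin 80 kg — magnitudes of an intensively farmed
  mid-size watershed.
- **Layout:** ~20 fields (10–40 ha, curve number 80–90, USLE K 0.2–0.4,
  LS 0.5–2) drain to a random tree of ~5 reaches with one outlet; zone flow
  paths have lags of 0.5–2 days, Δ 0.05–0.3, loss factors 0.9–1.0.

What it does **not** emulate: real geography or soils maps, regulatory
pesticide-use records, storm-scale (sub-daily) rainfall structure, spatial
correlation between fields, crop rotation, or management change over time.
Passing tests therefore demonstrate internal consistency, conservation, and
the algorithmic properties of the methods — not predictive skill against
field observations, which requires site data this package does not ship.

## Numerical choices and problem sizes

- All mass bookkeeping is float64; per-day closures are exact arithmetic
  identities and the global 19-year audit closes to ~10⁻¹⁴ relative.
- The packaged experiment sizes — a 3-year, two-application-per-year field
  for the discretization experiment and a 20-field/5-reach/19-year watershed
  for the conservation audit — were chosen as the smallest configurations
  that exercise multi-season carryover and a multi-reach network; both run
  in seconds.
- Degenerate inputs: zero flow days give zero capacity (everything
  deposits); zero suspended or bed mass guards all ratio-based pesticide
  fluxes to zero; zero-variance inputs to correlation and NSE raise.

## Known limitations

- No percolation/leaching or volatilization from soil; field losses are
  decay, runoff, and erosion only.
- Single particle-size class; no bedload; static channel geometry.
- Constant reach water volume (inflow passes through daily); no backwater or
  dynamic wave effects.
- Temperature-independent partitioning and decay.
- TU assumes strict concentration additivity and one test species.
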