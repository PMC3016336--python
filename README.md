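# pyresed

Coupled field/watershed simulation of sediment-associated pyrethroid
insecticides: erosion-driven removal of soil-bound pesticide from crop
fields, convolution routing through a channel network, in-stream suspended
solid and bed-sediment dynamics, water–sediment diffusive exchange, and
sediment toxicity expressed as organic-carbon-normalized toxic units (TU)
for the benthic amphipod *Hyalella azteca*.

The package is aimed at environmental-fate modelers and ecotoxicologists who
need daily, spatially resolved estimates of sediment-bound pesticide exposure
in agricultural watersheds — situations where monitoring data are sparse and
the compounds of interest (pyrethroids: K_OW 10⁵–10⁷) travel almost entirely
attached to particles, so dissolved-phase models miss most of the flux.

## What it computes

**Field scale.** A discretized soil column carries adsorbed and dissolved
pesticide per compartment. Eroded sediment removes adsorbed pesticide using a
*soil-interaction depth* D_E: the eroded-sediment concentration is a
return-to-unit weighted average over every compartment intersecting
[0, D_E],

    C_S,E = Σ_j w_j · C_s,j        (Σ w_j = 1)
    J_ER  = C_S,E · X_e · r_om · p

with X_e the MUSLE event soil loss (ton/day), r_om the organic-matter
enrichment ratio, and p = 10⁶ g/ton. Removal is applied per compartment as a
first-order loss term proportional to w_j·C_s,j, capped at availability.
Because the weights are defined on depth, not on the numerical grid, the
removal is invariant to compartment thickness — unlike the legacy behaviour
(also implemented, `mode="original"`) that strips only the top compartment
and underestimates removal badly on fine grids. Runoff is SCS curve-number;
dissolved extraction uses an exponential depth weighting over the top 2 cm.

**Routing.** Edge-of-field fluxes reach channel nodes by convolution with a
first-passage-time redistribution function

    U(t) = K · (1/t) · (4πΔ·t/T)^(−1/2) · exp(−(1 − t/T)² / (4Δ·t/T)),

an inverse-Gaussian density with lag time T, shear/storage parameter Δ, and
loss factor K. Daily kernels are built from the exact CDF, with in-transit
first-order decay at the aquatic half-life for pesticide.

**Channel.** Each reach keeps a completely mixed water column over an active
bed-sediment layer. Suspended solids relax toward a transport capacity
C_ss,max = SPCON·V^SPEXP (excess deposits, deficit resuspends, throttled by
channel erodibility and cover); adsorbed pesticide moves with the solid
fluxes; dissolved/adsorbed splits follow F_wd = 1/(1 + K_d·C_ss) in water and
F_dd = Φ/(Φ + (1−Φ)·ρ_s·K_d) in the bed; water–bed diffusion uses Mackay
two-film fugacity D-values; bed decay+burial is first order.

**Toxicity and statistics.** TU = Σ_i conc_i / LC50_i on the OC-normalized
scale (LC50s are 10-day *H. azteca* values for 1%-OC sediment), with method-
detection-limit censoring and the 0.01 display floor for non-detects; a
two-parameter logistic curve on log₁₀ TU links TU to observed mortality. The
stats module provides flow-weighted monthly aggregation, Pearson r with
two-tailed p, sequential variance decomposition, and grid-search calibration
of the USLE crop factor.

A packaged reference exposure table (19 years of annual maximum TU,
precipitation, and bifenthrin use) and a four-compound property table
(bifenthrin, λ-cyhalothrin, esfenvalerate, permethrin) ship with the package
(`pyresed.scenario.load_fixture`).

## Worked example

Exposure-driver statistics on the packaged reference table:

```text
$ pyresed stats
years with Sep-Oct bifenthrin use: 9
pearson r (use vs max TU): 0.74 (p = 0.022)
variance explained (use + precipitation): 90.1%
  share from Sep-Oct use:       54.9%
  share from Nov-Dec precipitation: 35.3%
```

Over the nine years with late-irrigation-season (September–October)
bifenthrin use, prior use correlates strongly with the following rainfall
season's maximum TU (r = 0.74, p = 0.022), and together with November–
December precipitation explains ~90% of its variance — use contributing
54.9% and precipitation 35.3%. Applied pyrethroid persists in soil through
the dry months and is mobilized by the first winter storms, which is why
late-season application timing, not annual total, drives peak toxicity.

Generate and run a small synthetic watershed:

```text
$ pyresed generate --seed 3 --n-fields 5 --n-reaches 2 --n-years 3 --outdir scn
wrote scenario (5 fields, 2 reaches, 3 years) to scn
$ pyresed simulate --scenario scn --outdir out
simulation complete; worst mass-balance relative error 2.715e-15
```

`out/` then holds one daily CSV per node (`flow_m3_d`, `ssc_kg_m3`,
per-compound water and bed concentrations, daily TU), a monthly outlet TU
series, and a mass-balance audit accounting for every gram applied
(soil storage and decay, routing losses, in-transit mass, in-reach decay,
bed storage, outlet export).

Library use mirrors the CLI:

```python
from pyresed.scenario import generate_watershed
from pyresed.simulate import run_simulation

scenario = generate_watershed(seed=1, n_fields=20, n_reaches=5, n_years=19)
result = run_simulation(scenario)
print(result.annual_max_tu())
print(result.audit["pesticide"]["bifenthrin"])
```

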