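# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `bluecarbon` pipeline. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The study design the package encodes

The pipeline reproduces a two-period blue-carbon budget for an urbanized
tropical estuary: five mangrove sites along an urbanization gradient
(scored 1–100), two sediment cores per site (one site has a single core),
cores 37–50 cm deep collected in 2016, sliced at 1 cm over 0–3 cm and 2 cm
below. Each core is dated radiometrically, mapped onto a *recent*
(1970–2016, 46 y) and a *historic* (1930–1970, 40 y) window, and summarized
as accretion rate (SAR), mass accretion rate (MAR), carbon density, carbon
burial rate (CBR) and carbon storage per period. Site values are then
upscaled to the estuary and balanced against watershed emissions.

The 1970 boundary is treated as exact (the field convention "approximately
the 1970s" is resolved to 1970.0); both period definitions and the
collection year are configurable.

## Synthetic data: what it emulates and what it does not

The generators produce cores, landscapes and demographic tables with known
truth, so that every downstream stage can be tested for *recovery* rather
than merely for internal consistency.

**Age model.** Truth is piecewise linear in depth with a single knot at the
1970 boundary — exactly two accretion rates per core, matching the
two-period analysis design. With a recent rate of 5 mm/y and collection in
2016 the boundary sits at 0.5 cm/y × 46 y = 23 cm.

**Radionuclides.** Excess ²¹⁰Pb at a slice equals the period's initial
activity decayed over the slice's true age, with the initial activity set
by supply over long-term mass flux: A₀ = flux / (SAR × mean DBD). Total
activity adds a constant supported background (default 20 Bq/kg). The
default supply values (0.008–0.06 Bq cm⁻² y⁻¹ depending on site) give
surface excess activities of roughly 100–400 Bq/kg, the range gamma
counting typically reports for rapidly accreting estuarine sediment.
¹³⁷Cs is a single-slice peak at the depth whose true age is 1963.

**Measurement noise.** Activities receive multiplicative lognormal noise
(default σ = 5%); bulk density, %C, %N and δ¹³C receive additive Gaussian
noise truncated at physical bounds (DBD floor 0.02 g/cm³, %C in [0, 100]).
The magnitudes of the compositional noise are assumptions — no error
magnitudes were available for them — and are configurable per scenario.

**Site presets.** Five scenarios ship with the package. Their recent-period
rates, bulk densities and isotope means target the published site-level
values where those are printed (e.g. 4.91 mm/y recent accretion and
0.096 g/cm³ recent carbon density at the clogged-canal site; 1.96 mm/y and
0.158 g/cm³ DBD at the low-density lagoon); historic rates for three sites
and all noise SDs are realistic presets, not ground-truth claims.

**Demography.** Defaults are the published watershed inputs: 769,000
people, 296,589 occupied households, 41,572 ha. The vehicle count is not
printed anywhere; the default of 298,000 is inferred so that the default
factor set reproduces the published 1.56 × 10⁶ Mg C y⁻¹ watershed total,
and is flagged as an inferred preset.

**Not emulated:** compaction, bioturbation/mixing, hurricane deposition
pulses, spatially correlated noise, or non-steady ²¹⁰Pb supply. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to these field phenomena.

## Chronology

**Supported background.** Two estimators are provided. The spec-simple one
averages the deepest *n* (default 3) total activities. The default
pipeline estimator fits A·exp(bz) + S to the deepest samples
(`fit_supported_background`): a 400-point grid search over S — scoring the
implied curve in linear space, since log-space residuals diverge as S
approaches the minimum total and would bias the search to S = 0 — seeds an
error-weighted `curve_fit`. The fit is used because the deepest-mean is
biased high whenever a fast-accreting core still carries excess at its
base, which compresses CRS ages. When the accretion history may contain a
rate change, the fitted tail should stay below it (the pipeline passes
`n_tail=6`); for a constant-rate core the whole profile is a single
exponential and the default (all samples) is the efficient choice.

**CRS.** Per-slice inventory is excess × DBD × thickness (Bq/cm²);
inventory below the core base is closed by an exponential fit to the
deepest three positive excess values (standard practice for truncated
cores). Ages on a 1-cm grid come from (1/λ) ln(I(0)/I(z)) with inventory
interpolated linearly in ln I between slice edges. 95% bounds are
first-order propagation of the per-slice activity errors through the
log-ratio (treating slice errors as independent); they quantify counting
error only, not model error, and are narrower than a full Bayesian
treatment would give. Ages are forced strictly decreasing (an infinitesimal
tie-break) so the age-mean curve is invertible. Depths with zero inventory
below them are reported as truncation, not extrapolated.

**CF:CS.** Least squares of ln(excess) on depth over slices with positive
excess (minimum 3); SAR = −λ/slope, CI from the t-based slope CI. A
non-negative slope raises `NoDecayTrendError`.

**¹³⁷Cs.** The marker is the deepest maximal slice above a detection
threshold (default 5 Bq/kg); ties are flagged and resolved deepest because
downward mixing smears peaks upward. Implied SAR = 10 × depth / (collection
− 1963).

A full Bayesian age-depth model is deliberately not re-implemented; its
output format (per-cm age means with 2.5/97.5% bounds) is accepted as an
imported chronology instead, which is the fidelity path when such output
is available. The original study also broadened that model's priors from
defaults without stating values; nothing here attempts to guess them.

## Per-core metrics

All formulas are the standard definitions (see README). Period windows are
found by inverting the age-mean curve; a period only partly covered by the
dated core is clipped and flagged truncated. At window edges, slices are
pro-rated by the depth fraction inside the window — under the locally
linear age model of a 1–2 cm slice this equals pro-rating by age fraction.
Window means of intensive quantities (DBD, %C, δ¹³C) use every slice that
intersects the window; pro-rating applies to the extensive storage
integral.

The depth extrapolation fits ln(storage per layer) against layer mid-depth
by least squares (non-positive layers excluded and counted), keeps observed
values where measured, fills modeled values elsewhere on a per-cm grid to
100 cm, and reports the cumulative stock and the top-25-cm fraction. For a
uniform profile the fraction is exactly 25%; for an exponential profile the
discrete ratio equals the analytic integral ratio because the midpoint
factors cancel.

Source attribution is box classification on the (δ¹³C, molar C/N) plane
against literature-derived endmember envelopes (mangrove leaves by species,
roots, POM, marine algae, seagrass). The shipped boxes are broad literature
ranges and configurable; no mixing model is attempted.

## Bootstrap

Per core, period and parameter: 1,000 draws, each the mean of a
with-replacement resample the size of the observation set (the resample
size is a documented choice; the source text does not state one). Derived
quantities resample each component independently, breaking depth pairing,
and evaluate the formula on the component resample means. Site pooling
concatenates core draw vectors (2,000 for two-core sites) — never
re-resamples. Percentiles are the inclusive empirical quantile with linear
interpolation (quantile conventions differ between environments, so this
is pinned). Significance is disjointness of the 2.5–97.5% bounds; a shared
endpoint counts as overlap (conservative). Storage is compared between
periods after normalizing by span. RNG streams are derived per (core,
period, parameter) from the master seed via a stable string hash, so
results are independent of execution order.

## Upscaling

IDW uses all samples with weight d⁻ᵖ (default p = 2; the exponent the
original interpolation used is unstated) and exact pass-through for cells
coinciding with a sample. The weight matrix depends only on geometry and
is precomputed once per component.

Site uncertainty is propagated by 100 bootstrap iterations drawing site
values from a Fernandez–Steel skew-normal (the family behind the
right-skewed sampler the original analysis used): a standard normal with
its two halves rescaled by ξ ≥ 1, standardized and then shifted/scaled so
the target mean and SD are matched *exactly* for any ξ; ξ is chosen to
minimize the squared mismatch of the 2.5/97.5% quantiles against the
supplied CI. Mean/SD are prioritized because the watershed totals — the
headline outputs — are linear in the site means; the three constraints are
generally incompatible. The reported SE is the standard deviation of
iteration sums, i.e. the dispersion across iterations, not the SE of their
mean.

The default desk-scale landscape uses 20 m cells (2 m cells are supported
but add nothing to correctness) sized so the mangrove area matches the
configured estuary area (default 2,312 ha, the value implied by the
published total-to-per-ha ratios; the true area behind those figures is
not printed and is treated as an input).

## Emission ledger

Per-unit aggregates ship as named defaults: 1.2 (residential electricity
per household), 2.2 (attributed commercial/industrial per household) and
1.85 (per vehicle) Mg C y⁻¹; users with primary factors can supply the
full chain (VMT, fuel efficiency, kg CO₂/gal). CO₂↔C conversions use the
exact molar ratio 12.011/44.009 — note the published pairing "1.2 Mg C ≡
4.6 t CO₂" does not match this ratio exactly (4.6 × 12.011/44.009 = 1.26);
the exact ratio is used and the aggregates are taken as printed. Offsets
are reported to the nearest 100, the precision at which such equivalences
are meaningful.

## Problem sizes

The shipped experiments use: 9 synthetic cores of 24 slices (45 cm);
1,000 bootstrap draws per core/period (100 upscaling iterations); 100
seeds for chronology recovery; 500 repeats for bootstrap coverage; 50
landscapes (10×10 cells, 6 sites) for upscaling recovery. These sizes give
Monte-Carlo error comfortably below the effects being checked while
keeping the whole suite fast on a single CPU.

## Known limitations

- CRS bounds reflect counting error only; no age-model structural error.
- The supported-background fit assumes one accretion rate over its tail;
  a rate change inside the tail window biases it (hence `n_tail=6` in the
  two-period pipeline).
- Box-based source classification is qualitative; overlapping endmember
  envelopes frequently yield multi-label or unclassified points.
- The emission ledger covers household electricity and personal vehicles
  only — no industrial point sources, land-use classes, or non-CO₂ gases.
- Interval-overlap significance is conservative relative to a formal test
  and is reported without multiple-testing correction, by design.
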