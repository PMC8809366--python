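# bluecarbon

Blue-carbon accounting for peri-urban mangrove forests: from radionuclide
core profiles to dated chronologies, period-resolved soil carbon burial and
storage with bootstrap uncertainty, estuary-wide spatial upscaling, and a
watershed anthropogenic-emission offset ledger.

## Who this is for

Coastal biogeochemists and blue-carbon analysts who need a tested,
reproducible pipeline for the standard chain of mangrove soil-carbon
calculations. The package targets the setting of an urbanized tropical
estuary — five mangrove sites along an urbanization gradient, two sediment
cores per site, a recent (1970–2016) and a historic (1930–1970) analysis
period — but every stage is a general-purpose library function.

## The methods at its core

**Pb-210 geochronology.** Excess (unsupported) ²¹⁰Pb decays with half-life
22.3 y over a supported background maintained by in-situ ²²⁶Ra. Two dating
models are built in: the constant-rate-of-supply (CRS) model, where the age
at depth *z* is

  t(z) = (1/λ) ln [ I(0) / I(z) ],

with I(z) the cumulative excess inventory below *z* (integrated over mass
depth, with an exponential-tail closure below the core base), and the
constant flux : constant sedimentation (CF:CS) model, where the accretion
rate is −λ / slope of ln(excess) vs depth. The supported background is
estimated from the deepest samples, either as their mean or by an
exponential-plus-constant fit; the ¹³⁷Cs 1963 fallout peak provides an
independent marker. Externally produced chronology tables (per-cm age
means with 2.5/97.5% bounds) are accepted as an alternative input.

**Carbon metrics.** With SAR the accretion rate (mm/y), DBD the dry bulk
density (g/cm³) and %C the carbon content:

  C density = DBD × %C/100 (g C/cm³)
  MAR = SAR/10 × DBD × 10⁴ (g m⁻² y⁻¹)
  CBR = MAR × %C/100 (g C m⁻² y⁻¹)
  C storage = ∫ C density dz × 100 (Mg C/ha)

Storage over periods of unequal length is normalized by the period span.

**Bootstrap inference.** 1,000 draws per core/period; derived quantities
resample each component independently (a DBD and a %C draw need not come
from the same depth); two-core sites pool 2,000 draws by concatenation;
significance is disjointness of the 2.5–97.5 percentile bounds.

**Estuary upscaling.** Site values spread over a mangrove cell grid by
inverse-distance-weighted interpolation, bootstrapped 100× with site values
drawn from right-skewed normal distributions matched to each site's mean,
SD and 95% CI. Aboveground biomass converts to carbon at 44% C content.

**Emission ledger.** Household electricity (residential 1.2 plus attributed
commercial/industrial 2.2 Mg C y⁻¹ per household) and vehicles (1.85 Mg C
y⁻¹ each) scale to watershed totals, per-area rates, and mangrove offset
equivalents.

## Worked example

```python
from bluecarbon import synthetic as syn, chronology as ch, metrics as met
import pandas as pd

scen = syn.DEFAULT_SCENARIOS["MPE"]          # clogged-canal site preset
core, truth = syn.generate_core(scen, seed=3)

mids = (core.depth_top_cm + core.depth_bottom_cm) / 2
prof = pd.DataFrame({
    "depth_mid_cm": mids,
    "pb210_total_bq_kg": core.pb210_total_bq_kg,
    "pb210_err_bq_kg": core.pb210_err_bq_kg,
    "cs137_bq_kg": core.cs137_bq_kg,
})
sup = ch.fit_supported_background(prof, n_tail=6)
chron = ch.crs_ages(prof, sup.mean_bq_kg, core.dbd_g_cm3.to_numpy(),
                    collection_year=2016,
                    thickness_cm=(core.depth_bottom_cm - core.depth_top_cm).to_numpy())
print(met.core_period_metrics(core, chron)[
    ["period", "sar_mm_y", "cbr_g_m2_y", "storage_mg_ha"]].round(2))
```

prints

```
     period  sar_mm_y  cbr_g_m2_y  storage_mg_ha
0    recent      5.57      525.39         208.06
1  historic      2.75      215.47          84.86
```

— the dated core recovers the preset's true accretion rates (4.91 mm/y
recent, 2.50 mm/y historic) to within the chronology's noise, and the
recent-period carbon burial rate (≈525 g C m⁻² y⁻¹) is roughly double the
historic one, the signature this kind of urbanized, low-flushing site
shows.

The full analysis is reproduced by the numbered drivers:

```bash
python analysis/01_simulate_cores.py 1      # nine-core synthetic estuary
python analysis/02_chronologies.py          # CRS dating + Cs-137 cross-check
python analysis/03_core_metrics.py          # period metrics, biplot, 1-m profile
python analysis/04_bootstrap_comparisons.py 1
python analysis/05_estuary_upscaling.py 1
python analysis/06_emissions_ledger.py 1
```

or end-to-end via the CLI: `bluecarbon run --seed 1 --out report`.

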