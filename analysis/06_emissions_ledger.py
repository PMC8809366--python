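"""Watershed anthropogenic-emission ledger and mangrove offset accounting.

Computes annual household/vehicle carbon emissions for the watershed,
expresses them per hectare, and balances them against the synthetic
estuary's mangrove sequestration from the upscaling stage.
"""

import json
import sys
from pathlib import Path

from bluecarbon import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "emissions"
OUT.mkdir(parents=True, exist_ok=True)

report = run_pipeline(PipelineConfig(seed=SEED))
ledger = report["emissions"]
with open(OUT / "ledger.json", "w") as fh:
    json.dump(ledger, fh, indent=2, default=float)

t = ledger["totals_mg_c_y"]
print("annual watershed emissions (Mg C/y):")
print(f"  residential electricity      {t['residential']:12,.0f}")
print(f"  commercial + industrial      {t['commercial_industrial']:12,.0f}")
print(f"  vehicles                     {t['vehicles']:12,.0f}")
print(f"  total                        {t['grand_total']:12,.0f}")
print(f"\nemission rate: {ledger['emission_rate_mg_c_ha_y']:.1f} Mg C/ha/y over the watershed")
print(f"mangrove sequestration: {report['sequestration_total_mg_c_y']:,.0f} Mg C/y "
      f"({report['sequestration_rate_mg_c_ha_y']:.2f} Mg C/ha/y)")
o = ledger["offsets"]
print(f"offsets: {o['households_electricity']:,} households (electricity), "
      f"{o['households_with_commercial_industrial']:,} incl. commercial/industrial, "
      f"{o['vehicles']:,} vehicles")
print(f"sequestration is {ledger['sequestration_pct_of_emissions']:.1f}% of the "
      f"emission rate; emissions exceed sequestration "
      f"{ledger['emissions_to_sequestration_ratio']:.0f}-fold")
print(f"\nwrote ledger.json to {OUT}")
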