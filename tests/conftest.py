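import numpy as np
import pandas as pd
import pytest

from bluecarbon import synthetic as syn


def constant_sar_scenario(sar_mm_y: float, **kw) -> syn.SiteScenario:
    """A scenario with one accretion rate for both periods."""
    defaults = dict(
        site_id="X",
        urban_index=50.0,
        flushing="low",
        sar_historic_mm_y=sar_mm_y,
        sar_recent_mm_y=sar_mm_y,
        dbd_mean_g_cm3=0.5,
        pctc_mean=10.0,
    )
    defaults.update(kw)
    return syn.SiteScenario(**defaults)


def radionuclide_profile(core_table: pd.DataFrame) -> pd.DataFrame:
    """Midpoint activity profile in the layout the dating functions take."""
    mids = (core_table["depth_top_cm"] + core_table["depth_bottom_cm"]) / 2.0
    return pd.DataFrame(
        {
            "depth_mid_cm": mids,
            "pb210_total_bq_kg": core_table["pb210_total_bq_kg"],
            "pb210_err_bq_kg": core_table["pb210_err_bq_kg"],
            "cs137_bq_kg": core_table["cs137_bq_kg"],
        }
    )


@pytest.fixture
def clean_core():
    """Zero-noise constant-SAR (3 mm/y) core with truth."""
    scen = constant_sar_scenario(3.0)
    table, truth = syn.generate_core(scen, noise_scale=0.0, seed=0)
    return scen, table, truth


@pytest.fixture
def piecewise_core():
    """Zero-noise core with recent 5 mm/y over historic 2.5 mm/y."""
    scen = constant_sar_scenario(5.0, sar_historic_mm_y=2.5)
    table, truth = syn.generate_core(scen, noise_scale=0.0, seed=0)
    return scen, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
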