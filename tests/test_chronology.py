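"""Dating models: decay correction, supported background, CRS, CF:CS, Cs-137."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bluecarbon import chronology as ch
from bluecarbon import synthetic as syn

from conftest import constant_sar_scenario, radionuclide_profile


def _exact_profile(sar_mm_y=3.0, supported=20.0, a0=250.0, depths=None):
    """Closed-form excess exponential over a background, no noise."""
    if depths is None:
        depths = np.arange(1.0, 40.0, 2.0)  # midpoints of contiguous 2-cm slices
    r = sar_mm_y / 10.0
    excess = a0 * np.exp(-ch.LAMBDA_PB210 * depths / r)
    return pd.DataFrame(
        {
            "depth_mid_cm": depths,
            "pb210_total_bq_kg": excess + supported,
            "pb210_err_bq_kg": 0.05 * (excess + supported),
            "cs137_bq_kg": 0.0,
        }
    )


class TestDecayCorrect:
    @pytest.mark.parametrize(
        "activity,elapsed,expected",
        [(10.0, 0.0, 10.0), (10.0, 22.3, 20.0), (10.0, 44.6, 40.0)],
    )
    def test_half_life_arithmetic(self, activity, elapsed, expected):
        assert ch.decay_correct(activity, elapsed) == pytest.approx(expected)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            ch.decay_correct(10.0, -1.0)

    @given(
        a=st.floats(0.1, 1e3),
        t1=st.floats(0.0, 100.0),
        t2=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_correction_composes(self, a, t1, t2):
        once = ch.decay_correct(ch.decay_correct(a, t1), t2)
        assert once == pytest.approx(ch.decay_correct(a, t1 + t2), rel=1e-12)


class TestSupported:
    def test_constant_deepest_recovered_exactly(self):
        prof = _exact_profile()
        prof.loc[prof.index[-3:], "pb210_total_bq_kg"] = 20.0
        est = ch.estimate_supported(prof, n_deepest=3)
        assert est.mean_bq_kg == pytest.approx(20.0)
        assert est.se_bq_kg == pytest.approx(0.0)

    def test_flat_profile_flags_no_excess(self):
        prof = _exact_profile(a0=0.0)
        est = ch.estimate_supported(prof)
        assert est.no_excess

    def test_too_few_deepest_rejected(self):
        with pytest.raises(ValueError):
            ch.estimate_supported(_exact_profile(), n_deepest=1)

    def test_background_fit_recovers_supported_with_residual_excess(self):
        # deepest samples still hold excess: the plain mean is biased high,
        # the exponential+background fit is not
        prof = _exact_profile(sar_mm_y=6.0, supported=15.0)
        fit = ch.fit_supported_background(prof)
        assert fit.mean_bq_kg == pytest.approx(15.0, abs=0.5)
        naive = ch.estimate_supported(prof)
        assert naive.mean_bq_kg > fit.mean_bq_kg + 1.0


class TestCRS:
    def test_surface_age_is_collection_year(self):
        prof = _exact_profile()
        chron = ch.crs_ages(prof, 20.0, 0.5, collection_year=2016, thickness_cm=2.0)
        assert chron.ages["age_mean_yr_ce"].iloc[0] == pytest.approx(2016.0, abs=1e-6)

    @pytest.mark.parametrize("sar", [2.0, 3.0, 5.0])
    def test_constant_rate_closed_form_ages(self, sar):
        prof = _exact_profile(sar_mm_y=sar)
        chron = ch.crs_ages(prof, 20.0, 0.5, collection_year=2016, thickness_cm=2.0)
        z = chron.ages["depth_cm"].to_numpy()
        expected = 2016.0 - z / (sar / 10.0)
        np.testing.assert_allclose(
            chron.ages["age_mean_yr_ce"].to_numpy(), expected, atol=0.35
        )

    def test_half_inventory_depth_is_one_half_life(self):
        sar = 4.0
        prof = _exact_profile(sar_mm_y=sar, depths=np.arange(0.25, 60.0, 0.5))
        chron = ch.crs_ages(prof, 20.0, 0.5, collection_year=2016, thickness_cm=0.5)
        # inventory halves where age(z) = 22.3 y, i.e. z = r x 22.3
        z_half = (sar / 10.0) * 22.3
        age = chron.age_at(z_half)
        assert 2016.0 - age == pytest.approx(22.3, rel=0.02)

    def test_no_excess_anywhere_rejected(self):
        prof = _exact_profile(a0=0.0)
        with pytest.raises(ValueError):
            ch.crs_ages(prof, 20.0, 0.5, collection_year=2016)

    def test_bounds_bracket_means(self):
        prof = _exact_profile()
        chron = ch.crs_ages(prof, 20.0, 0.5, collection_year=2016, thickness_cm=2.0)
        assert (chron.ages["age_lo2p5_yr_ce"] <= chron.ages["age_mean_yr_ce"]).all()
        assert (chron.ages["age_hi97p5_yr_ce"] >= chron.ages["age_mean_yr_ce"]).all()


class TestCFCS:
    def test_slope_to_rate_arithmetic(self):
        # slope -0.1 per cm turns into lambda/0.1 cm/y = 3.108 mm/y
        depths = np.arange(0.5, 30.0, 2.0)
        excess = 300.0 * np.exp(-0.1 * depths)
        prof = pd.DataFrame(
            {"depth_mid_cm": depths, "pb210_total_bq_kg": excess + 20.0}
        )
        sar, _ = ch.cfcs_rate(prof, 20.0)
        assert sar == pytest.approx(3.108, abs=1e-3)

    def test_recovers_generating_rate_exactly(self, clean_core):
        scen, table, _ = clean_core
        sar, (lo, hi) = ch.cfcs_rate(radionuclide_profile(table), scen.supported_bq_kg)
        assert sar == pytest.approx(scen.sar_recent_mm_y, rel=1e-9)
        assert lo <= sar <= hi

    def test_two_points_rejected(self):
        prof = _exact_profile(depths=np.array([0.5, 2.5]))
        with pytest.raises(ValueError):
            ch.cfcs_rate(prof, 20.0)

    def test_increasing_activity_raises_no_decay_trend(self):
        depths = np.arange(0.5, 20.0, 2.0)
        prof = pd.DataFrame(
            {"depth_mid_cm": depths, "pb210_total_bq_kg": 30.0 + depths}
        )
        with pytest.raises(ch.NoDecayTrendError):
            ch.cfcs_rate(prof, 20.0)


class TestAccretion:
    def test_linear_ages_give_constant_rate(self):
        years = 2016.0 - 5.0 * np.arange(0.0, 30.0)  # 5 y per cm
        chron = ch.Chronology(
            ages=pd.DataFrame(
                {
                    "depth_cm": np.arange(0.0, 30.0),
                    "age_mean_yr_ce": years,
                    "age_lo2p5_yr_ce": years - 1.0,
                    "age_hi97p5_yr_ce": years + 1.0,
                }
            )
        )
        acc = ch.accretion_at_depth(chron)
        np.testing.assert_allclose(acc["sar_mm_y"], 2.0)

    def test_piecewise_rates_recovered_per_segment(self, piecewise_core):
        scen, table, truth = piecewise_core
        prof = radionuclide_profile(table)
        chron = ch.crs_ages(
            prof,
            scen.supported_bq_kg,
            table["dbd_g_cm3"].to_numpy(),
            collection_year=2016,
            thickness_cm=(table["depth_bottom_cm"] - table["depth_top_cm"]).to_numpy(),
        )
        acc = chron.accretion_mm_y
        z1 = truth.boundary_depth_cm
        recent = acc.loc[acc["depth_cm"] < z1 - 2, "sar_mm_y"].mean()
        historic = acc.loc[acc["depth_cm"] > z1 + 2, "sar_mm_y"].mean()
        assert recent == pytest.approx(5.0, rel=0.05)
        assert historic == pytest.approx(2.5, rel=0.05)

    def test_non_monotone_ages_rejected_at_construction(self):
        years = np.array([2016.0, 2010.0, 2012.0])
        with pytest.raises(ValueError):
            ch.Chronology(
                ages=pd.DataFrame(
                    {
                        "depth_cm": [0.0, 1.0, 2.0],
                        "age_mean_yr_ce": years,
                        "age_lo2p5_yr_ce": years,
                        "age_hi97p5_yr_ce": years,
                    }
                )
            )


class TestCs137:
    def test_peak_depth_implies_rate(self):
        # peak at 12 cm with 2016 collection: 120 mm over 53 y = 2.264 mm/y
        depths = np.arange(1.0, 30.0, 1.0)
        cs = np.zeros_like(depths)
        cs[depths == 12.0] = 30.0
        prof = pd.DataFrame(
            {"depth_mid_cm": depths, "pb210_total_bq_kg": 20.0, "cs137_bq_kg": cs}
        )
        res = ch.cs137_depth(prof, collection_year=2016)
        assert res["peak_depth_cm"] == 12.0
        assert res["implied_sar_mm_y"] == pytest.approx(2.264, abs=1e-3)

    def test_below_threshold_returns_none(self):
        prof = pd.DataFrame(
            {"depth_mid_cm": [1.0, 2.0, 3.0], "pb210_total_bq_kg": 20.0, "cs137_bq_kg": 1.0}
        )
        assert ch.cs137_depth(prof, threshold_bq_kg=5.0, collection_year=2016) is None

    def test_tie_resolves_deepest_and_flags(self):
        prof = pd.DataFrame(
            {
                "depth_mid_cm": [1.0, 5.0, 9.0],
                "pb210_total_bq_kg": 20.0,
                "cs137_bq_kg": [30.0, 10.0, 30.0],
            }
        )
        res = ch.cs137_depth(prof, collection_year=2016)
        assert res["peak_depth_cm"] == 9.0
        assert res["tie"]


class TestChronologyIO:
    def test_csv_round_trip_lossless(self, tmp_path, clean_core):
        scen, table, _ = clean_core
        prof = radionuclide_profile(table)
        chron = ch.crs_ages(
            prof, scen.supported_bq_kg, 0.5, collection_year=2016, thickness_cm=2.0
        )
        path = tmp_path / "chron.csv"
        chron.to_csv(path)
        back = ch.Chronology.read_csv(path)
        pd.testing.assert_frame_equal(
            chron.ages[ch.CHRONOLOGY_COLUMNS].reset_index(drop=True),
            back.ages.reset_index(drop=True),
        )
        assert back.provenance == "imported"


def test_three_dating_methods_agree_at_zero_noise(clean_core):
    """CRS, CF:CS, and the Cs-137 marker agree on SAR within 1%."""
    scen, table, _ = clean_core
    prof = radionuclide_profile(table)
    cfcs, _ = ch.cfcs_rate(prof, scen.supported_bq_kg)
    chron = ch.crs_ages(
        prof,
        scen.supported_bq_kg,
        table["dbd_g_cm3"].to_numpy(),
        collection_year=2016,
        thickness_cm=(table["depth_bottom_cm"] - table["depth_top_cm"]).to_numpy(),
    )
    crs = chron.accretion_mm_y["sar_mm_y"].iloc[:30].mean()
    cs = ch.cs137_depth(prof, collection_year=2016)
    true = scen.sar_recent_mm_y
    assert cfcs == pytest.approx(true, rel=0.01)
    assert crs == pytest.approx(true, rel=0.01)
    # Cs-137 peak is quantized to slice midpoints: allow one half-slice
    assert cs["implied_sar_mm_y"] * 53.0 / 10.0 == pytest.approx(
        true * 53.0 / 10.0, abs=1.0
    )
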