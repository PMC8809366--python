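"""Carbon metric formulas, period windows, extrapolation, source boxes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bluecarbon import chronology as ch
from bluecarbon import metrics as met


def _linear_chronology(years_per_cm=5.0, depth_max=30.0, collection=2016.0):
    z = np.arange(0.0, depth_max + 0.5)
    years = collection - years_per_cm * z
    return ch.Chronology(
        ages=pd.DataFrame(
            {
                "depth_cm": z,
                "age_mean_yr_ce": years,
                "age_lo2p5_yr_ce": years - 1.0,
                "age_hi97p5_yr_ce": years + 1.0,
            }
        )
    )


def _uniform_profile(n=20, thick=2.0, dbd=0.5, pct_c=10.0):
    tops = thick * np.arange(n)
    return pd.DataFrame(
        {
            "depth_top_cm": tops,
            "depth_bottom_cm": tops + thick,
            "dbd_g_cm3": dbd,
            "pct_c": pct_c,
            "pct_n": 0.5,
            "d13c_permil": -27.0,
        }
    )


class TestIsotopeUtilities:
    @pytest.mark.parametrize(
        "ratio_factor,expected", [(1.0, 0.0), (1.01, 10.0), (0.99, -10.0)]
    )
    def test_delta_notation(self, ratio_factor, expected):
        assert met.delta_notation(0.0112 * ratio_factor, 0.0112) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            met.delta_notation(0.0, 0.0112)

    @pytest.mark.parametrize(
        "pct_c,pct_n,expected",
        [(12.011, 14.007, 1.0), (40.0, 2.0, 23.32), (0.0, 5.0, 0.0)],
    )
    def test_molar_cn(self, pct_c, pct_n, expected):
        assert met.molar_cn(pct_c, pct_n) == pytest.approx(expected, abs=0.005)

    def test_zero_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            met.molar_cn(10.0, 0.0)


class TestRateFormulas:
    @pytest.mark.parametrize(
        "dbd,pct_c,expected", [(1.0, 100.0, 1.0), (0.2, 15.0, 0.03), (0.5, 0.0, 0.0)]
    )
    def test_carbon_density(self, dbd, pct_c, expected):
        assert met.carbon_density(dbd, pct_c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "sar,dbd,expected", [(5.0, 1.0, 5000.0), (0.0, 0.7, 0.0), (1.96, 0.158, 309.7)]
    )
    def test_mass_accretion_rate(self, sar, dbd, expected):
        assert met.mass_accretion_rate(sar, dbd) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "sar,dbd,pct_c,expected",
        [(4.91, 1.0, 9.6, 471.4), (0.0, 1.0, 50.0, 0.0), (2.0, 0.5, 10.0, 100.0)],
    )
    def test_carbon_burial_rate(self, sar, dbd, pct_c, expected):
        assert met.carbon_burial_rate(sar, dbd, pct_c) == pytest.approx(expected, abs=0.05)

    @given(
        sar=st.floats(0.1, 10.0),
        dbd=st.floats(0.05, 2.0),
        pct_c=st.floats(0.0, 60.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_cbr_equals_mar_times_carbon_fraction(self, sar, dbd, pct_c):
        assert met.carbon_burial_rate(sar, dbd, pct_c) == pytest.approx(
            met.mass_accretion_rate(sar, dbd) * pct_c / 100.0, rel=1e-12
        )


class TestPeriodWindows:
    def test_linear_inversion_by_hand(self):
        # 5 y/cm, collection 2016: 1970 at 9.2 cm, 1930 at 17.2 cm
        windows = {w.period: w for w in met.assign_period_windows(_linear_chronology())}
        assert windows["recent"].depth_top_cm == pytest.approx(0.0)
        assert windows["recent"].depth_bottom_cm == pytest.approx(9.2)
        assert windows["historic"].depth_top_cm == pytest.approx(9.2)
        assert windows["historic"].depth_bottom_cm == pytest.approx(17.2)
        assert not windows["historic"].truncated

    def test_bottom_age_1950_truncates_historic(self):
        chron = _linear_chronology(years_per_cm=5.0, depth_max=13.0)  # bottom 1951
        windows = {w.period: w for w in met.assign_period_windows(chron)}
        assert windows["historic"].truncated
        assert windows["historic"].span_years < 40.0
        assert not windows["recent"].truncated

    def test_chronology_outside_periods_empty(self):
        chron = _linear_chronology(years_per_cm=0.2, depth_max=10.0)  # ends 2014
        windows = met.assign_period_windows(chron, {"historic": (1930.0, 1970.0)})
        assert windows == []


class TestStorage:
    def test_uniform_density_window(self):
        profile = _uniform_profile(dbd=0.5, pct_c=10.0)  # C density 0.05
        w = met.PeriodWindow("recent", 1970, 2016, 5.0, 15.0, 46.0)
        assert met.carbon_storage(profile, w) == pytest.approx(50.0)

    def test_zero_thickness_window(self):
        profile = _uniform_profile()
        w = met.PeriodWindow("recent", 1970, 2016, 5.0, 5.0, 46.0)
        assert met.carbon_storage(profile, w) == 0.0

    @given(split=st.floats(1.0, 19.0))
    @settings(max_examples=40, derandomize=True)
    def test_additivity_over_depth_partition(self, split):
        profile = _uniform_profile(dbd=0.4, pct_c=12.0)
        whole = met.PeriodWindow("all", 0, 1, 0.0, 20.0, 1.0)
        left = met.PeriodWindow("a", 0, 1, 0.0, split, 1.0)
        right = met.PeriodWindow("b", 0, 1, split, 20.0, 1.0)
        assert met.carbon_storage(profile, left) + met.carbon_storage(
            profile, right
        ) == pytest.approx(met.carbon_storage(profile, whole), rel=1e-12)

    def test_invariant_to_reslicing(self):
        coarse = _uniform_profile(n=5, thick=4.0)
        fine = _uniform_profile(n=20, thick=1.0)
        w = met.PeriodWindow("x", 0, 1, 3.0, 17.0, 1.0)
        assert met.carbon_storage(coarse, w) == pytest.approx(
            met.carbon_storage(fine, w)
        )

    @pytest.mark.parametrize(
        "storage,span,expected", [(92.0, 46.0, 2.0), (40.0, 40.0, 1.0), (0.0, 10.0, 0.0)]
    )
    def test_normalize_by_period(self, storage, span, expected):
        w = met.PeriodWindow("p", 0, span, 0.0, 1.0, span)
        assert met.normalize_by_period(storage, w) == pytest.approx(expected)
        assert met.normalize_by_period(storage, w) * w.span_years == pytest.approx(storage)

    def test_zero_span_rejected(self):
        w = met.PeriodWindow("p", 1970, 1970, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            met.normalize_by_period(10.0, w)


class TestDepthExtrapolation:
    def test_constant_profile_top_quarter_exact(self):
        layers = pd.DataFrame({"depth_cm": np.arange(0.5, 40.0), "storage": 2.0})
        res = met.extrapolate_storage_profile(layers)
        assert res["fraction_top"] == pytest.approx(0.25)

    def test_exponential_matches_analytic_integral(self):
        k = 0.03
        z = np.arange(0.5, 40.0)
        layers = pd.DataFrame({"depth_cm": z, "storage": 5.0 * np.exp(-k * z)})
        res = met.extrapolate_storage_profile(layers)
        analytic = (1 - np.exp(-25 * k)) / (1 - np.exp(-100 * k))
        assert res["fraction_top"] == pytest.approx(analytic, rel=0.005)

    def test_observed_full_span_changes_nothing(self):
        z = np.arange(0.5, 100.0)
        layers = pd.DataFrame({"depth_cm": z, "storage": 3.0 * np.exp(-0.01 * z)})
        res = met.extrapolate_storage_profile(layers)
        np.testing.assert_allclose(
            res["profile"]["storage"].to_numpy(), layers["storage"].to_numpy(), rtol=1e-9
        )

    def test_nonpositive_layers_excluded_and_counted(self):
        z = np.arange(0.5, 30.0)
        s = 4.0 * np.exp(-0.02 * z)
        s[5] = 0.0
        layers = pd.DataFrame({"depth_cm": z, "storage": s})
        assert met.extrapolate_storage_profile(layers)["n_excluded"] == 1


class TestSourceClassification:
    def test_point_in_single_box(self):
        assert met.classify_source(-25.0, 11.0) == ["POM"]

    def test_point_in_overlap_gets_both_labels(self):
        labels = met.classify_source(-27.5, 35.0)
        assert "mangrove roots" in labels
        assert len(labels) >= 2

    def test_point_outside_all_boxes_unclassified(self):
        assert met.classify_source(-5.0, 100.0) == ["unclassified"]

    def test_malformed_box_rejected(self):
        with pytest.raises(ValueError):
            met.classify_source(-27.0, 20.0, {"bad": (-20.0, -25.0, 5.0, 10.0)})

    def test_biplot_table_shape(self):
        profile = _uniform_profile(n=6)
        table = met.biplot_table(profile)
        assert len(table) == 6
        assert {"depth_mid_cm", "d13c_permil", "cn_molar", "sources"} <= set(table.columns)
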