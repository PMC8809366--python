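"""Per-core, per-period carbon metrics.

Definitions (standard soil blue-carbon bookkeeping):

* C density (g C/cm^3)  = DBD x %C/100
* MAR (g m^-2 y^-1)     = SAR(cm/y) x DBD x 10^4
* CBR (g C m^-2 y^-1)   = MAR x %C/100 = SAR(cm/y) x C density x 10^4
* C storage (Mg C/ha)   = depth-integrated C density x 100 (1 g/cm^2 = 100 Mg/ha)

plus the isotope utilities (delta notation, molar C/N), period-window
assignment by inverting an age-depth chronology, log-linear depth
extrapolation of the storage profile, and box-based endmember source
classification for the d13C vs C/N biplot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MOLAR_MASS_C = 12.011
MOLAR_MASS_N = 14.007

#: Default analysis periods: recent = protection/urbanization era up to the
#: 2016 collection; historic = the post-agricultural recovery decades.
DEFAULT_PERIODS = {"recent": (1970.0, 2016.0), "historic": (1930.0, 1970.0)}


@dataclass
class PeriodWindow:
    """A core depth range mapped to a named time period."""

    period: str
    year_start: float
    year_end: float
    depth_top_cm: float
    depth_bottom_cm: float
    span_years: float
    truncated: bool = False

    @property
    def thickness_cm(self) -> float:
        return self.depth_bottom_cm - self.depth_top_cm


def delta_notation(r_sample: float, r_standard: float) -> float:
    """Isotope delta value in per-mil: [(Rsample/Rstandard) - 1] x 10^3."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1e3


def molar_cn(pct_c, pct_n):
    """Molar C/N ratio from mass percents."""
    pct_n = np.asarray(pct_n, dtype=float)
    if np.any(pct_n <= 0):
        raise ValueError("%N must be positive for a molar ratio")
    out = (np.asarray(pct_c, dtype=float) / MOLAR_MASS_C) / (pct_n / MOLAR_MASS_N)
    return float(out) if out.ndim == 0 else out


def carbon_density(dbd_g_cm3, pct_c):
    """Carbon mass per soil volume, g C/cm^3."""
    return np.asarray(dbd_g_cm3, dtype=float) * np.asarray(pct_c, dtype=float) / 100.0


def mass_accretion_rate(sar_mm_y, dbd_g_cm3):
    """Dry-mass accumulation rate, g m^-2 y^-1."""
    return (np.asarray(sar_mm_y, dtype=float) / 10.0) * np.asarray(dbd_g_cm3, dtype=float) * 1e4


def carbon_burial_rate(sar_mm_y, dbd_g_cm3, pct_c):
    """Carbon mass accumulation rate, g C m^-2 y^-1."""
    return mass_accretion_rate(sar_mm_y, dbd_g_cm3) * np.asarray(pct_c, dtype=float) / 100.0


def assign_period_windows(chronology, periods: dict | None = None) -> list[PeriodWindow]:
    """Map named year spans onto core depth ranges via the age-mean curve.

    A period only partially covered by the dated core comes back truncated
    (flagged, with the year span clipped to what the core records); a
    period entirely outside the chronology yields no window.
    """
    if periods is None:
        periods = DEFAULT_PERIODS
    ages = chronology.ages
    year_top = float(ages["age_mean_yr_ce"].iloc[0])
    year_bottom = float(ages["age_mean_yr_ce"].iloc[-1])
    windows: list[PeriodWindow] = []
    for name, (y0, y1) in periods.items():
        lo, hi = min(y0, y1), max(y0, y1)
        # clip to the span the chronology records
        eff_lo, eff_hi = max(lo, year_bottom), min(hi, year_top)
        if eff_hi <= eff_lo:
            continue
        truncated = (eff_lo > lo + 1e-9) or (eff_hi < hi - 1e-9)
        windows.append(
            PeriodWindow(
                period=name,
                year_start=eff_lo,
                year_end=eff_hi,
                depth_top_cm=float(chronology.depth_of_year(eff_hi)),
                depth_bottom_cm=float(chronology.depth_of_year(eff_lo)),
                span_years=eff_hi - eff_lo,
                truncated=truncated,
            )
        )
    return windows


def _overlap_fraction(top, bottom, w_top, w_bottom):
    """Fraction of the [top, bottom) slice inside the window depth span."""
    thick = bottom - top
    ov = np.minimum(bottom, w_bottom) - np.maximum(top, w_top)
    return np.clip(ov, 0.0, None) / thick


def window_observations(profile: pd.DataFrame, window: PeriodWindow, columns=None) -> pd.DataFrame:
    """Depth-slice observations falling (at least partly) in a window.

    These are the per-slice values a period bootstrap resamples; slices
    straddling a window edge are included (their values are point
    measurements, pro-rating applies to extensive sums, not to them).
    """
    if columns is None:
        columns = ["dbd_g_cm3", "pct_c", "pct_n", "d13c_permil"]
    frac = _overlap_fraction(
        profile["depth_top_cm"].to_numpy(dtype=float),
        profile["depth_bottom_cm"].to_numpy(dtype=float),
        window.depth_top_cm,
        window.depth_bottom_cm,
    )
    keep = [c for c in columns if c in profile.columns]
    return profile.loc[frac > 0, keep].reset_index(drop=True)


def carbon_storage(profile: pd.DataFrame, window: PeriodWindow) -> float:
    """Depth-integrated carbon stock over a window, Mg C/ha.

    Sums C density x thickness over the slices intersecting the window,
    pro-rating edge slices by the fraction of their thickness inside it.
    """
    top = profile["depth_top_cm"].to_numpy(dtype=float)
    bottom = profile["depth_bottom_cm"].to_numpy(dtype=float)
    frac = _overlap_fraction(top, bottom, window.depth_top_cm, window.depth_bottom_cm)
    cdens = carbon_density(profile["dbd_g_cm3"].to_numpy(), profile["pct_c"].to_numpy())
    return float(np.sum(cdens * (bottom - top) * frac) * 100.0)


def normalize_by_period(storage_mg_ha: float, window: PeriodWindow) -> float:
    """Storage per year of the window span, Mg ha^-1 y^-1.

    Periods of unequal length (46 recent vs 40 historic years) are made
    comparable by dividing by the span.
    """
    if window.span_years <= 0:
        raise ValueError("window span must be positive")
    return storage_mg_ha / window.span_years


def extrapolate_storage_profile(
    layer_storage: pd.DataFrame, depth_max_cm: float = 100.0, top_cm: float = 25.0
) -> dict:
    """Extend a per-layer storage profile to depth with a log-linear model.

    Fits ln(storage) against layer mid-depth by least squares (non-positive
    layers are excluded and flagged), fills unobserved 1-cm depths with the
    modeled values, and reports the cumulative stock to ``depth_max_cm``
    and the fraction held in the top ``top_cm``.
    """
    df = layer_storage.sort_values("depth_cm").reset_index(drop=True)
    z = df["depth_cm"].to_numpy(dtype=float)
    s = df["storage"].to_numpy(dtype=float)
    pos = s > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 layers with positive storage")
    slope, intercept = np.polyfit(z[pos], np.log(s[pos]), 1)

    grid = np.arange(0.5, depth_max_cm, 1.0)  # per-cm layer midpoints
    modeled = np.exp(intercept + slope * grid)
    observed_mask = (grid >= z.min()) & (grid <= z.max())
    filled = modeled.copy()
    filled[observed_mask] = np.interp(grid[observed_mask], z[pos], s[pos])

    cum_total = float(np.sum(filled))
    cum_top = float(np.sum(filled[grid < top_cm]))
    return {
        "profile": pd.DataFrame({"depth_cm": grid, "storage": filled}),
        "slope_per_cm": float(slope),
        "fraction_top": cum_top / cum_total,
        "stock_to_max_mg_ha": cum_total,
        "n_excluded": int((~pos).sum()),
    }


#: Literature-style endmember boxes for the d13C vs molar C/N biplot:
#: (d13c_lo, d13c_hi, cn_lo, cn_hi). Configurable; these are broad
#: literature-derived envelopes, not measured values.
DEFAULT_ENDMEMBERS = {
    "mangrove leaves (red)": (-31.0, -27.0, 25.0, 60.0),
    "mangrove leaves (white)": (-30.0, -26.5, 20.0, 45.0),
    "mangrove leaves (black)": (-28.5, -25.0, 15.0, 40.0),
    "mangrove roots": (-29.5, -25.5, 30.0, 90.0),
    "POM": (-26.0, -20.0, 5.0, 12.0),
    "marine algae": (-22.0, -16.0, 4.0, 10.0),
    "seagrass": (-15.0, -8.0, 12.0, 25.0),
}


def classify_source(
    d13c_permil: float, cn_molar: float, endmembers: dict | None = None
) -> list[str]:
    """All endmember boxes containing a (d13C, C/N) point.

    Overlapping boxes can both claim a point; an empty result is reported
    as ["unclassified"].
    """
    boxes = DEFAULT_ENDMEMBERS if endmembers is None else endmembers
    labels = []
    for name, (d_lo, d_hi, c_lo, c_hi) in boxes.items():
        if d_lo > d_hi or c_lo > c_hi:
            raise ValueError(f"malformed endmember box {name!r}")
        if d_lo <= d13c_permil <= d_hi and c_lo <= cn_molar <= c_hi:
            labels.append(name)
    return labels or ["unclassified"]


def biplot_table(profile: pd.DataFrame, endmembers: dict | None = None) -> pd.DataFrame:
    """Biplot-ready table: per slice d13C, molar C/N, and source labels."""
    cn = molar_cn(profile["pct_c"].to_numpy(), profile["pct_n"].to_numpy())
    labels = [
        ";".join(classify_source(d, c, endmembers))
        for d, c in zip(profile["d13c_permil"], np.atleast_1d(cn))
    ]
    mid = (profile["depth_top_cm"] + profile["depth_bottom_cm"]) / 2.0
    return pd.DataFrame(
        {
            "depth_mid_cm": mid,
            "d13c_permil": profile["d13c_permil"],
            "cn_molar": np.atleast_1d(cn),
            "sources": labels,
        }
    )


def core_period_metrics(
    profile: pd.DataFrame,
    chronology,
    periods: dict | None = None,
) -> pd.DataFrame:
    """Per-period summary metrics for one core.

    SAR is the mean accretion rate over the window's depth span; DBD/%C
    are window means; derived metrics use the identities above. One row
    per period.
    """
    from .chronology import accretion_at_depth

    windows = assign_period_windows(chronology, periods)
    acc = chronology.accretion_mm_y
    if acc is None:
        acc = accretion_at_depth(chronology)
    rows = []
    for w in windows:
        in_win = (acc["depth_cm"] >= w.depth_top_cm) & (acc["depth_cm"] < w.depth_bottom_cm)
        sar = float(acc.loc[in_win, "sar_mm_y"].mean()) if in_win.any() else (
            10.0 * w.thickness_cm / w.span_years
        )
        obs = window_observations(profile, w)
        dbd = float(obs["dbd_g_cm3"].mean())
        pct_c = float(obs["pct_c"].mean())
        storage = carbon_storage(profile, w)
        rows.append(
            {
                "period": w.period,
                "depth_top_cm": w.depth_top_cm,
                "depth_bottom_cm": w.depth_bottom_cm,
                "span_years": w.span_years,
                "truncated": w.truncated,
                "sar_mm_y": sar,
                "dbd_g_cm3": dbd,
                "pct_c": pct_c,
                "d13c_permil": float(obs["d13c_permil"].mean()),
                "c_density_g_cm3": float(carbon_density(dbd, pct_c)),
                "mar_g_m2_y": float(mass_accretion_rate(sar, dbd)),
                "cbr_g_m2_y": float(carbon_burial_rate(sar, dbd, pct_c)),
                "storage_mg_ha": storage,
                "storage_norm_mg_ha_y": normalize_by_period(storage, w),
            }
        )
    return pd.DataFrame(rows)
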