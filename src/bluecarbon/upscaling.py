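"""Estuary-wide upscaling of site carbon values.

Site-level means are spread over the mangrove cell grid by
inverse-distance-weighted (IDW) interpolation; measurement uncertainty is
propagated by bootstrapping the interpolation (default 100 iterations),
each iteration drawing one value per site from a right-skewed normal
distribution fitted to that site's mean, SD, and 95% CI. Watershed totals
are the across-iteration mean of sum(cell value x cell area), with the SD
of iteration sums reported as the iteration SE.

The right-skewed family is the Fernandez–Steel skew-normal: a standard
normal with its two halves rescaled by a skew parameter xi >= 1 (xi = 1 is
symmetric, larger xi pushes mass to the right tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

N_ITER_DEFAULT = 100
IDW_POWER_DEFAULT = 2.0

SCALING_COMPONENTS = [
    "aboveground storage",
    "aboveground accumulation",
    "soil storage recent",
    "soil storage historic",
    "soil burial recent",
    "soil burial historic",
]


@dataclass
class MangroveGrid:
    """Cell centers with a mangrove mask; only flagged cells get values."""

    x: np.ndarray
    y: np.ndarray
    cell_area_m2: float
    mangrove: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mangrove = np.asarray(self.mangrove, dtype=bool)
        if self.cell_area_m2 <= 0:
            raise ValueError("cell area must be positive")

    @property
    def mangrove_area_ha(self) -> float:
        return float(self.mangrove.sum() * self.cell_area_m2 / 1e4)

    def to_ascii(self, path, values=None) -> None:
        """Plain-text raster (ESRI ASCII-grid layout) of the mangrove mask
        or of per-cell values."""
        xs, ys = np.unique(self.x), np.unique(self.y)
        ncols, nrows = len(xs), len(ys)
        cell = float(xs[1] - xs[0]) if ncols > 1 else np.sqrt(self.cell_area_m2)
        vals = self.mangrove.astype(float) if values is None else np.asarray(values, float)
        grid = np.full((nrows, ncols), -9999.0)
        ix = np.searchsorted(xs, self.x)
        iy = np.searchsorted(ys, self.y)
        grid[iy, ix] = vals
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\nnrows {nrows}\n")
            fh.write(f"xllcorner {xs[0] - cell / 2}\nyllcorner {ys[0] - cell / 2}\n")
            fh.write(f"cellsize {cell}\nNODATA_value -9999\n")
            for row in grid[::-1]:  # north-up row order
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "MangroveGrid":
        header = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines[:6]:
            k, v = line.split()
            header[k.lower()] = float(v)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
        data = np.loadtxt(lines[6:]).reshape(nrows, ncols)[::-1]
        xs = header["xllcorner"] + cell * (np.arange(ncols) + 0.5)
        ys = header["yllcorner"] + cell * (np.arange(nrows) + 0.5)
        gx, gy = np.meshgrid(xs, ys)
        mask = (data != header.get("nodata_value", -9999.0)) & (data > 0)
        return cls(x=gx.ravel(), y=gy.ravel(), cell_area_m2=cell**2, mangrove=mask.ravel())


@dataclass
class ScalingResult:
    component: str
    units: str
    cell_means: np.ndarray
    watershed_sum_mean: float
    watershed_sum_se: float
    per_ha_mean: float
    n_iter: int


class SkewNormal:
    """Fernandez–Steel skew-normal, standardized then shifted/scaled.

    The raw variate Y has density 2/(xi + 1/xi) [phi(y/xi) for y >= 0;
    phi(y xi) for y < 0], xi >= 1 right-skewed. The delivered variate is
    mean + sd * (Y - E[Y]) / sqrt(Var[Y]), so mean and sd are matched
    exactly for any xi.
    """

    def __init__(self, mean: float, sd: float, xi: float = 1.0):
        if sd < 0:
            raise ValueError("sd must be non-negative")
        if xi < 1.0:
            raise ValueError("skew parameter xi must be >= 1 (right-skewed)")
        self.mean, self.sd, self.xi = float(mean), float(sd), float(xi)
        m1 = np.sqrt(2.0 / np.pi)
        self._mu_y = m1 * (xi - 1.0 / xi)
        ey2 = (xi**3 + xi**-3) / (xi + 1.0 / xi)
        self._sigma_y = np.sqrt(ey2 - self._mu_y**2)

    def _ppf_raw(self, q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        xi = self.xi
        p_neg = 1.0 / (xi**2 + 1.0)  # P(Y < 0)
        lower = q < p_neg
        out = np.empty_like(q)
        # y < 0 branch: F(y) = 2/((xi+1/xi) xi) Phi(y xi)
        out[lower] = stats.norm.ppf(q[lower] * (xi + 1.0 / xi) * xi / 2.0) / xi
        # y >= 0 branch: F(y) = p_neg + 2 xi/(xi+1/xi) (Phi(y/xi) - 1/2)
        qq = (q[~lower] - p_neg) * (xi + 1.0 / xi) / (2.0 * xi) + 0.5
        out[~lower] = stats.norm.ppf(qq) * xi
        return out

    def ppf(self, q):
        scalar = np.isscalar(q)
        if self.sd == 0:
            out = np.full_like(np.atleast_1d(np.asarray(q, dtype=float)), self.mean)
        else:
            z = (self._ppf_raw(q) - self._mu_y) / self._sigma_y
            out = self.mean + self.sd * z
        return float(out[0]) if scalar else out

    def rvs(self, size, rng) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        return self.ppf(rng.random(size))


def fit_right_skew_normal(mean: float, sd: float, ci: tuple[float, float], xi_max: float = 8.0) -> SkewNormal:
    """Fit a right-skewed normal to (mean, sd, 95% CI).

    Mean and SD are matched exactly; the skew parameter xi >= 1 minimizes
    the squared mismatch of the 2.5/97.5% quantiles against the supplied
    CI (the three constraints are generally incompatible, and the mean
    drives the upscaled totals). sd = 0 degenerates to a point mass.
    """
    lo, hi = ci
    if lo > hi:
        raise ValueError("CI lower bound exceeds upper bound")
    if sd == 0:
        return SkewNormal(mean, 0.0)

    def loss(xi):
        d = SkewNormal(mean, sd, xi)
        q = d.ppf(np.array([0.025, 0.975]))
        return (q[0] - lo) ** 2 + (q[1] - hi) ** 2

    res = optimize.minimize_scalar(loss, bounds=(1.0, xi_max), method="bounded")
    xi = float(res.x)
    if loss(1.0) <= res.fun + 1e-12:  # symmetric CI: stay at the bound
        xi = 1.0
    return SkewNormal(mean, sd, xi)


def idw_interpolate(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    cell_xy: np.ndarray,
    power: float = IDW_POWER_DEFAULT,
    eps: float = 1e-9,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation onto cell centers.

    Every sample contributes to every cell with weight d^-power; a cell
    within ``eps`` of a sample takes that sample's value exactly.
    """
    sample_xy = np.atleast_2d(np.asarray(sample_xy, dtype=float))
    sample_values = np.asarray(sample_values, dtype=float)
    cell_xy = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    if sample_xy.shape[0] == 0:
        raise ValueError("need at least one sample")
    if power <= 0:
        raise ValueError("power must be positive")
    return idw_weights(sample_xy, cell_xy, power=power, eps=eps) @ sample_values


def idw_weights(
    sample_xy: np.ndarray,
    cell_xy: np.ndarray,
    power: float = IDW_POWER_DEFAULT,
    eps: float = 1e-9,
) -> np.ndarray:
    """Row-normalized IDW weight matrix (cells x samples).

    Depends only on the geometry, so repeated interpolations of new sample
    values reduce to a matrix product.
    """
    sample_xy = np.atleast_2d(np.asarray(sample_xy, dtype=float))
    cell_xy = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    d = np.sqrt(
        (cell_xy[:, None, 0] - sample_xy[None, :, 0]) ** 2
        + (cell_xy[:, None, 1] - sample_xy[None, :, 1]) ** 2
    )
    exact = d < eps
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[has_exact] = exact[has_exact].astype(float)  # coincident cell: that sample
    return w / w.sum(axis=1, keepdims=True)


def bootstrap_upscale(
    samples: pd.DataFrame,
    grid: MangroveGrid,
    n_iter: int = N_ITER_DEFAULT,
    power: float = IDW_POWER_DEFAULT,
    seed: int = 0,
) -> ScalingResult:
    """Bootstrapped IDW upscaling of one component to the watershed.

    ``samples`` columns: site_id, x, y, component, mean, sd, ci_lo, ci_hi,
    units (one row per site, one shared component).
    """
    comps = samples["component"].unique()
    if len(comps) != 1:
        raise ValueError(f"mixed components in one upscale: {list(comps)}")
    units = samples["units"].iloc[0]
    rng = np.random.default_rng(seed)
    dists = [
        fit_right_skew_normal(r["mean"], r["sd"], (r["ci_lo"], r["ci_hi"]))
        for r in samples.to_dict("records")
    ]
    xy = samples[["x", "y"]].to_numpy(dtype=float)
    cells = np.column_stack([grid.x[grid.mangrove], grid.y[grid.mangrove]])
    area_ha = grid.cell_area_m2 / 1e4

    weights = idw_weights(xy, cells, power=power)
    cell_acc = np.zeros(cells.shape[0])
    sums = np.empty(n_iter)
    for it in range(n_iter):
        vals = np.array([d.rvs(1, rng)[0] for d in dists], dtype=float)
        cell_vals = weights @ vals
        cell_acc += cell_vals
        sums[it] = cell_vals.sum() * area_ha  # Mg/ha x ha per cell
    cell_means = cell_acc / n_iter
    return ScalingResult(
        component=str(comps[0]),
        units=units,
        cell_means=cell_means,
        watershed_sum_mean=float(sums.mean()),
        watershed_sum_se=float(sums.std(ddof=1)) if n_iter > 1 else 0.0,
        per_ha_mean=float(sums.mean() / grid.mangrove_area_ha),
        n_iter=n_iter,
    )


def aboveground_carbon(biomass_mg: float, fraction: float = 0.44) -> float:
    """Carbon in aboveground biomass, assuming 44% C content by default."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("carbon fraction must be in [0, 1]")
    if biomass_mg < 0:
        raise ValueError("biomass must be non-negative")
    return biomass_mg * fraction


def summarize_estuary(results: dict[str, ScalingResult], mangrove_area_ha: float) -> pd.DataFrame:
    """Estuary totals table plus the combined sequestration rate.

    The combined rate (aboveground accumulation + recent soil burial,
    Mg ha^-1 y^-1) is appended as its own row when both components exist.
    """
    if mangrove_area_ha <= 0:
        raise ValueError("mangrove area must be positive")
    rows = []
    for comp, res in results.items():
        rows.append(
            {
                "component": comp,
                "total": res.watershed_sum_mean,
                "se": res.watershed_sum_se,
                "per_ha": res.watershed_sum_mean / mangrove_area_ha,
                "units": res.units,
            }
        )
    df = pd.DataFrame(rows)
    above = df.loc[df["component"] == "aboveground accumulation", "per_ha"]
    soil = df.loc[df["component"] == "soil burial recent", "per_ha"]
    if len(above) and len(soil):
        combined = float(above.iloc[0] + soil.iloc[0])
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [
                        {
                            "component": "combined sequestration rate",
                            "total": combined * mangrove_area_ha,
                            "se": np.nan,
                            "per_ha": combined,
                            "units": "Mg/ha/y",
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return df
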