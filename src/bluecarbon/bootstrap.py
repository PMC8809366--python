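"""Resampling machinery for per-core, per-period inference.

Each parameter gets 1,000 bootstrap draws per core/period: a draw is the
mean of a with-replacement resample of the observations (or, for derived
quantities, the formula evaluated on independently resampled components —
a DBD and a %C draw need not come from the same depth). The draw mean is
the point estimate; the empirical 2.5th/97.5th percentiles are the 95%
bounds. Sites with two cores pool draws by concatenation (2,000 values).
Significance between two estimates is interval disjointness — no
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics

N_BOOT_DEFAULT = 1000


@dataclass
class BootstrapEstimate:
    parameter: str
    label: str  # core or site id
    period: str
    draws: np.ndarray
    seed: int | None = None
    truncated: bool = False
    mean: float = field(init=False)
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.mean = float(np.mean(self.draws))
        # inclusive empirical quantile with linear interpolation
        self.lower = float(np.percentile(self.draws, 2.5))
        self.upper = float(np.percentile(self.draws, 97.5))


def substream_seed(master_seed: int, *names) -> int:
    """Deterministic per-(core, period, parameter) seed below 2^31."""
    h = (int(master_seed) * 2654435761) % (2**61 - 1)
    for name in names:
        for ch in str(name):
            h = ((h ^ ord(ch)) * 1099511628211) % (2**61 - 1)
    return h % (2**31 - 1)


def bootstrap_mean(
    values,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    parameter: str = "",
    label: str = "",
    period: str = "",
) -> BootstrapEstimate:
    """Percentile bootstrap of a sample mean.

    Resample size equals the number of observations (standard
    nonparametric bootstrap).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    draws = values[idx].mean(axis=1)
    return BootstrapEstimate(parameter, label, period, draws, seed=seed)


_FORMULAS = {
    "c_density": lambda c: metrics.carbon_density(c["dbd"], c["pct_c"]),
    "mar": lambda c: metrics.mass_accretion_rate(c["sar"], c["dbd"]),
    "cbr": lambda c: metrics.carbon_burial_rate(c["sar"], c["dbd"], c["pct_c"]),
    # storage = mean C density over the window x window thickness x 100
    "storage": lambda c: metrics.carbon_density(c["dbd"], c["pct_c"])
    * c["thickness_cm"]
    * 100.0,
}


def bootstrap_derived(
    component_sets: dict,
    formula: str,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    constants: dict | None = None,
    parameter: str | None = None,
    label: str = "",
    period: str = "",
) -> BootstrapEstimate:
    """Random-pairing bootstrap of a derived quantity.

    Each draw resamples every component set independently (so pairings
    across depth are broken), takes each component's resample mean, and
    evaluates the formula on those means. ``constants`` supplies scalar
    inputs (e.g. the window thickness for storage).
    """
    if formula not in _FORMULAS:
        raise ValueError(f"unknown formula {formula!r}")
    sets = {k: np.asarray(v, dtype=float) for k, v in component_sets.items()}
    for name, vals in sets.items():
        if vals.size == 0:
            raise ValueError(f"component set {name!r} is empty")
    rng = np.random.default_rng(seed)
    comp_draws = {}
    for name, vals in sets.items():
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        comp_draws[name] = vals[idx].mean(axis=1)
    if constants:
        comp_draws.update(constants)
    draws = _FORMULAS[formula](comp_draws)
    draws = np.broadcast_to(np.asarray(draws, dtype=float), (n_boot,)).copy()
    return BootstrapEstimate(parameter or formula, label, period, draws, seed=seed)


def combine_cores_site(core_estimates: list[BootstrapEstimate], site: str | None = None) -> BootstrapEstimate:
    """Site-level pooling: concatenate core draw vectors, never re-resample.

    Two-core sites yield 2,000 pooled draws; single-core sites pass
    through. The pooled bounds widen when the two cores disagree.
    """
    if not core_estimates:
        raise ValueError("no estimates to combine")
    first = core_estimates[0]
    for e in core_estimates[1:]:
        if e.parameter != first.parameter or e.period != first.period:
            raise ValueError("cannot pool estimates of different parameters/periods")
    draws = np.concatenate([e.draws for e in core_estimates])
    return BootstrapEstimate(
        first.parameter,
        site or first.label,
        first.period,
        draws,
        truncated=any(e.truncated for e in core_estimates),
    )


def bounds_overlap_test(a: BootstrapEstimate, b: BootstrapEstimate) -> str:
    """'significant' iff the 95% bounds are disjoint; a shared endpoint
    counts as overlap (conservative)."""
    disjoint = a.upper < b.lower or b.upper < a.lower
    return "significant" if disjoint else "not_significant"


def compare_periods(est_a: BootstrapEstimate, est_b: BootstrapEstimate) -> dict:
    """Within-core recent-vs-historic comparison with direction."""
    if est_a.label != est_b.label or est_a.parameter != est_b.parameter:
        raise ValueError("period comparison requires one core and one parameter")
    if est_a.period == est_b.period:
        raise ValueError("need two different periods")
    result = bounds_overlap_test(est_a, est_b)
    if est_a.mean == est_b.mean:
        direction = "equal"
    else:
        hi, lo = (est_a, est_b) if est_a.mean > est_b.mean else (est_b, est_a)
        direction = f"{hi.period} > {lo.period}"
    return {
        "label": est_a.label,
        "parameter": est_a.parameter,
        "result": result,
        "direction": direction,
        "truncated": est_a.truncated or est_b.truncated,
    }
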