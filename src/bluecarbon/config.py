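"""Pipeline configuration: defaults, YAML I/O, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Long-term sea-level rise trends (mm/y) from the two regional tide gauges,
#: used only as comparison constants for accretion rates.
SLR_TRENDS_MM_Y = {
    "san_juan": (2.09, 0.37),
    "magueyes": (1.90, 0.30),
}


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis.

    ``core_tables`` empty means "simulate the bundled synthetic scenario".
    ``chronology_tables`` maps core ids to externally produced per-cm
    chronology CSVs; cores without an entry are dated internally (CRS).
    """

    core_tables: list[str] = field(default_factory=list)
    chronology_tables: dict = field(default_factory=dict)
    grid_path: str | None = None
    samples_path: str | None = None

    periods: dict = field(
        default_factory=lambda: {"recent": (1970.0, 2016.0), "historic": (1930.0, 1970.0)}
    )
    collection_year: int = 2016
    seed: int = 1
    n_boot: int = 1000
    n_iter: int = 100
    idw_power: float = 2.0
    soil_depth_cap_cm: float = 28.0  # depth limit for estuary-wide soil storage
    mangrove_area_ha: float = 2312.3
    noise_scale: float = 1.0
    slr_trends_mm_y: dict = field(default_factory=lambda: dict(SLR_TRENDS_MM_Y))

    #: per-site aboveground carbon presets (storage Mg/ha, accumulation
    #: Mg/ha/y) ingested as site values, not estimated here
    aboveground: dict = field(
        default_factory=lambda: {
            "MPW": {"storage": 80.0, "storage_sd": 12.0, "accum": 4.6, "accum_sd": 0.7},
            "MPE": {"storage": 95.0, "storage_sd": 14.0, "accum": 5.5, "accum_sd": 0.8},
            "SJ": {"storage": 85.0, "storage_sd": 13.0, "accum": 4.9, "accum_sd": 0.7},
            "Torr": {"storage": 92.0, "storage_sd": 14.0, "accum": 5.3, "accum_sd": 0.8},
            "Pin": {"storage": 98.0, "storage_sd": 15.0, "accum": 5.7, "accum_sd": 0.9},
        }
    )

    #: cores whose DBD column is substituted from a donor core (logged)
    donor_dbd: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_boot < 1 or self.n_iter < 1:
            raise ValueError("n_boot and n_iter must be positive")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be positive")
        for p in self.core_tables:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in self.chronology_tables.values():
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.periods = {k: tuple(v) for k, v in cfg.periods.items()}
        return cfg
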