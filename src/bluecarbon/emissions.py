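"""Watershed anthropogenic CO2/C emission ledger and mangrove offsets.

Household electricity (residential plus attributed commercial/industrial)
and personal-vehicle fuel use are converted to annual carbon emissions,
expressed per watershed area, and balanced against the mangrove forest's
annual carbon sequestration: how many households or vehicles does the
forest offset, and what fraction of the watershed emission rate does the
sequestration rate represent?
"""

from __future__ import annotations

from dataclasses import dataclass, field

MOLAR_MASS_C = 12.011
MOLAR_MASS_CO2 = 44.009

#: Published per-unit carbon aggregates (Mg C y^-1): residential electricity
#: per household, attributed commercial+industrial electricity per household,
#: and per-vehicle fuel use.
DEFAULT_FACTORS = {
    "residential_mg_c_per_household": 1.2,
    "commercial_industrial_mg_c_per_household": 2.2,
    "per_vehicle_mg_c": 1.85,
}


def co2_to_carbon(mass_co2_mg: float) -> float:
    """Mg CO2 -> Mg C via the molar-mass ratio 12.011/44.009."""
    if mass_co2_mg < 0:
        raise ValueError("mass must be non-negative")
    return mass_co2_mg * MOLAR_MASS_C / MOLAR_MASS_CO2


def carbon_to_co2(mass_c_mg: float) -> float:
    """Mg C -> Mg CO2 (inverse of :func:`co2_to_carbon`)."""
    if mass_c_mg < 0:
        raise ValueError("mass must be non-negative")
    return mass_c_mg * MOLAR_MASS_CO2 / MOLAR_MASS_C


def household_emissions(
    households: int,
    residential_factor: float = DEFAULT_FACTORS["residential_mg_c_per_household"],
    commercial_industrial_factor: float = DEFAULT_FACTORS[
        "commercial_industrial_mg_c_per_household"
    ],
) -> dict:
    """Annual household-attributed carbon emissions, Mg C y^-1, by component."""
    if households < 0 or residential_factor < 0 or commercial_industrial_factor < 0:
        raise ValueError("inputs must be non-negative")
    res = households * residential_factor
    ci = households * commercial_industrial_factor
    return {"residential": res, "commercial_industrial": ci, "total": res + ci}


def vehicle_emissions(
    vehicles: int,
    vmt_mi_y: float | None = None,
    mpg: float | None = None,
    ef_co2_kg_per_gal: float | None = None,
    per_vehicle_mg_c: float | None = None,
) -> float:
    """Annual vehicle carbon emissions, Mg C y^-1.

    Either supply the full factor chain (annual vehicle-miles traveled,
    fuel efficiency, and a CO2 emission factor per gallon) or a published
    per-vehicle carbon aggregate.
    """
    if vehicles < 0:
        raise ValueError("vehicle count must be non-negative")
    if per_vehicle_mg_c is not None:
        return vehicles * per_vehicle_mg_c
    if vmt_mi_y is None or mpg is None or ef_co2_kg_per_gal is None:
        return vehicles * DEFAULT_FACTORS["per_vehicle_mg_c"]
    if mpg <= 0:
        raise ValueError("fuel efficiency must be positive")
    gallons = vmt_mi_y / mpg
    co2_mg = gallons * ef_co2_kg_per_gal * 1e-3
    return vehicles * co2_to_carbon(co2_mg)


def per_area_rates(total_c_mg_y: float, population: int, area_ha: float) -> dict:
    """Watershed emission rate (Mg C ha^-1 y^-1) and population density
    (persons km^-2)."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    return {
        "emission_rate_mg_c_ha_y": total_c_mg_y / area_ha,
        "population_density_km2": population / (area_ha / 100.0),
    }


def offset_equivalents(
    sequestration_mg_c_y: float,
    per_household: float = DEFAULT_FACTORS["residential_mg_c_per_household"],
    per_household_with_ci: float = DEFAULT_FACTORS["residential_mg_c_per_household"]
    + DEFAULT_FACTORS["commercial_industrial_mg_c_per_household"],
    per_vehicle: float = DEFAULT_FACTORS["per_vehicle_mg_c"],
) -> dict:
    """How many households/vehicles the annual sequestration offsets.

    Reported to the nearest 100, the precision at which such equivalences
    are meaningful.
    """
    if min(per_household, per_household_with_ci, per_vehicle) <= 0:
        raise ValueError("offset factors must be positive")

    def near100(x: float) -> int:
        return int(round(x / 100.0) * 100)

    return {
        "households_electricity": near100(sequestration_mg_c_y / per_household),
        "households_with_commercial_industrial": near100(
            sequestration_mg_c_y / per_household_with_ci
        ),
        "vehicles": near100(sequestration_mg_c_y / per_vehicle),
    }


def sequestration_fraction(seq_rate: float, emission_rate: float) -> float:
    """Sequestration as a percentage of the emission rate (same units)."""
    if emission_rate <= 0:
        raise ValueError("emission rate must be positive")
    return 100.0 * seq_rate / emission_rate


@dataclass
class EmissionInventory:
    """Full watershed ledger computed from demographic counts and factors."""

    population: int
    occupied_households: int
    vehicles: int
    watershed_area_ha: float
    residential_mg_c_per_household: float = DEFAULT_FACTORS[
        "residential_mg_c_per_household"
    ]
    commercial_industrial_mg_c_per_household: float = DEFAULT_FACTORS[
        "commercial_industrial_mg_c_per_household"
    ]
    per_vehicle_mg_c: float = DEFAULT_FACTORS["per_vehicle_mg_c"]
    totals: dict = field(init=False)

    def __post_init__(self) -> None:
        hh = household_emissions(
            self.occupied_households,
            self.residential_mg_c_per_household,
            self.commercial_industrial_mg_c_per_household,
        )
        veh = vehicle_emissions(self.vehicles, per_vehicle_mg_c=self.per_vehicle_mg_c)
        self.totals = {**hh, "vehicles": veh, "grand_total": hh["total"] + veh}

    def ledger(self, sequestration_mg_c_y: float, seq_rate_mg_c_ha_y: float) -> dict:
        """Offset accounting against a mangrove sequestration total/rate."""
        rates = per_area_rates(
            self.totals["grand_total"], self.population, self.watershed_area_ha
        )
        return {
            "totals_mg_c_y": self.totals,
            **rates,
            "offsets": offset_equivalents(
                sequestration_mg_c_y,
                self.residential_mg_c_per_household,
                self.residential_mg_c_per_household
                + self.commercial_industrial_mg_c_per_household,
                self.per_vehicle_mg_c,
            ),
            "sequestration_pct_of_emissions": sequestration_fraction(
                seq_rate_mg_c_ha_y, rates["emission_rate_mg_c_ha_y"]
            ),
            "emissions_to_sequestration_ratio": self.totals["grand_total"]
            / sequestration_mg_c_y,
        }
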