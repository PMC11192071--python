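"""Sweet-potato carrying-capacity model for rock-garden area estimates.

Converts hectares of rock-garden (lithic-mulch) cultivation into daily
caloric yield and the population that yield could support, across cultivation
regimes (continuous; shifting 5 years off / 5 on; shifting 15 off / 3 on)
and low/high soil-nitrogen yield scenarios:

    energy [kcal/day]   = land [ha] * yield [t/ha/yr] * 2809 [kcal/day per t/yr]
    individuals         = floor(energy / 2785 [kcal/person/day])

Shifting cultivation scales the land simultaneously in production by its
duty cycle years_on / (years_on + years_off): 1/2 for the 5/5 regime and
1/6 for the 15/3 regime.  (An alternative convention states the 15/3 factor
as 25 %; the published per-regime land areas are consistent with 1/6, which
is therefore the default — the 25 % convention is available via
``use_quarter_for_15_3``.)

Published-table constants are retained so computed values can be checked
against, and discrepancies flagged relative to, the printed record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

KCAL_PER_TON_YEAR = 2809.0     # kcal/day produced by 1 ton/year of sweet potato
KCAL_PER_PERSON_DAY = 2785.0   # maximum daily requirement per person


@dataclass(frozen=True)
class CapacityConstants:
    kcal_per_ton_year: float = KCAL_PER_TON_YEAR
    kcal_per_person_day: float = KCAL_PER_PERSON_DAY

    def __post_init__(self) -> None:
        if self.kcal_per_ton_year <= 0 or self.kcal_per_person_day <= 0:
            raise ValueError("constants must be positive")


@dataclass(frozen=True)
class CultivationRegime:
    name: str
    years_on: float
    years_off: float

    @property
    def land_fraction(self) -> float:
        return self.years_on / (self.years_on + self.years_off)


CONTINUOUS = CultivationRegime("continuous", 1.0, 0.0)
SHIFTING_5_5 = CultivationRegime("shifting_5_5", 5.0, 5.0)
SHIFTING_15_3 = CultivationRegime("shifting_15_3", 3.0, 15.0)
REGIMES = {r.name: r for r in (CONTINUOUS, SHIFTING_5_5, SHIFTING_15_3)}

#: Sweet-potato yield (tons/ha/year) by (regime, N availability).
DEFAULT_YIELDS = {
    ("continuous", "low"): 1.46,
    ("continuous", "high"): 5.09,
    ("shifting_5_5", "low"): 2.38,
    ("shifting_5_5", "high"): 8.00,
    ("shifting_15_3", "low"): 5.61,
    ("shifting_15_3", "high"): 17.60,
}

#: Garden-area sources of the published comparison: this study's island-wide
#: SWIR-derived estimate versus the earlier VNIR-derived estimate.
DEFAULT_AREA_SOURCES = {"this_study": 760.0, "comparison": 3133.9}

#: Published reference values (energy kcal/day, individuals) for the
#: 12-row capacity table, keyed (source, regime, n_level).  Used only for
#: flagging print/arithmetic discrepancies, never as computation inputs.
PUBLISHED_TABLE = {
    ("comparison", "continuous", "low"): (12_852_562.6, 4614),
    ("comparison", "continuous", "high"): (44_807_906.8, 16089),
    ("comparison", "shifting_5_5", "low"): (10_475_384.6, 3761),
    ("comparison", "shifting_5_5", "high"): (35_211_376.8, 12643),
    ("comparison", "shifting_15_3", "low"): (8_230_659.3, 2955),
    ("comparison", "shifting_15_3", "high"): (25_821_676.3, 9271),
    ("this_study", "continuous", "low"): (3_116_886.4, 1119),
    ("this_study", "continuous", "high"): (10_866_335.6, 3901),
    ("this_study", "shifting_5_5", "low"): (2_540_459.6, 912),
    ("this_study", "shifting_5_5", "high"): (8_539_360.0, 3066),
    ("this_study", "shifting_15_3", "low"): (1_996_075.4, 716),
    ("this_study", "shifting_15_3", "high"): (6_262_384.6, 2248),
}


def land_available(total_area_ha: float,
                   regime: CultivationRegime | str,
                   use_quarter_for_15_3: bool = False) -> float:
    """Hectares simultaneously in production under a cultivation regime.

    Full precision; display rounding happens at reporting edges.
    """
    if total_area_ha < 0:
        raise ValueError("total_area_ha must be nonnegative")
    if isinstance(regime, str):
        regime = REGIMES[regime]
    if use_quarter_for_15_3 and regime.name == "shifting_15_3":
        return total_area_ha * 0.25
    return total_area_ha * regime.land_fraction


def displayed_land(land_ha: float) -> float:
    """Land rounded to the published table's display precision.

    The published table truncates large (>= 500 ha) values at one decimal
    (1566.95 -> 1566.9) and rounds smaller values at two decimals
    (126.666... -> 126.67); its energy column is arithmetically derived from
    these displayed values.
    """
    if land_ha >= 500:
        return math.floor(land_ha * 10 + 1e-9) / 10
    return round(land_ha, 2)


def energy_yield(area_ha: float, yield_t_ha_yr: float,
                 constants: CapacityConstants | None = None) -> float:
    """Daily caloric yield (kcal/day) of an area under a given yield."""
    if area_ha < 0 or yield_t_ha_yr < 0:
        raise ValueError("inputs must be nonnegative")
    c = constants or CapacityConstants()
    return area_ha * yield_t_ha_yr * c.kcal_per_ton_year


def supported_population(energy_kcal_day: float,
                         constants: CapacityConstants | None = None) -> int:
    """Individuals supported: floor of energy over per-person requirement."""
    if energy_kcal_day < 0:
        raise ValueError("energy must be nonnegative")
    c = constants or CapacityConstants()
    return int(math.floor(energy_kcal_day / c.kcal_per_person_day))


@dataclass
class CapacityResult:
    source: str
    regime: str
    n_level: str
    yield_t_ha_yr: float
    land_available_ha: float
    energy_kcal_day: float
    individuals: int
    published_energy: float | None = None
    published_individuals: int | None = None
    energy_discrepant: bool = False


def capacity_table(total_areas: dict | None = None,
                   yields: dict | None = None,
                   constants: CapacityConstants | None = None,
                   use_quarter_for_15_3: bool = False,
                   energy_tolerance: float = 0.1) -> list[CapacityResult]:
    """Cross-product capacity table: area sources x regimes x N levels.

    Each row applies :func:`land_available`, :func:`energy_yield` (on the
    display-precision land value, matching the published table's arithmetic)
    and :func:`supported_population`.  Where a published reference value
    exists, rows whose computed energy differs from it by more than
    ``energy_tolerance`` kcal/day are flagged ``energy_discrepant``.
    """
    areas = total_areas if total_areas is not None else DEFAULT_AREA_SOURCES
    ytab = yields if yields is not None else DEFAULT_YIELDS
    c = constants or CapacityConstants()
    rows: list[CapacityResult] = []
    for source, total in areas.items():
        for regime in ("continuous", "shifting_5_5", "shifting_15_3"):
            for n_level in ("low", "high"):
                y = ytab[(regime, n_level)]
                land = displayed_land(
                    land_available(total, regime, use_quarter_for_15_3))
                energy = energy_yield(land, y, c)
                indiv = supported_population(energy, c)
                pub = PUBLISHED_TABLE.get((source, regime, n_level))
                pub_e, pub_i = pub if pub else (None, None)
                rows.append(CapacityResult(
                    source=source, regime=regime, n_level=n_level,
                    yield_t_ha_yr=y, land_available_ha=land,
                    energy_kcal_day=energy, individuals=indiv,
                    published_energy=pub_e, published_individuals=pub_i,
                    energy_discrepant=(
                        pub_e is not None
                        and abs(energy - pub_e) > energy_tolerance)))
    return rows


def capacity_frame(rows: list[CapacityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class DietAdjustedCapacity:
    base_mean: float
    adjusted: float
    supplement_fraction: float
    base_rounded: int
    adjusted_rounded: int


def diet_adjusted(results: list[CapacityResult],
                  supplement_fraction: float = 0.5) -> DietAdjustedCapacity:
    """Mean scenario capacity, raised by a non-garden food supplement.

    The base is the unweighted mean of the scenario ``individuals`` values;
    the adjustment multiplies by (1 + supplement_fraction) to account for
    marine and additional terrestrial foods.  Rounded figures are to the
    nearest thousand.
    """
    if not results:
        raise ValueError("at least one result required")
    base = sum(r.individuals for r in results) / len(results)
    adjusted = base * (1.0 + supplement_fraction)
    return DietAdjustedCapacity(
        base_mean=base, adjusted=adjusted,
        supplement_fraction=supplement_fraction,
        base_rounded=int(round(base, -3)),
        adjusted_rounded=int(round(adjusted, -3)))
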