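"""Global annual Fe release by the chinstrap penguin population.

The year is split in two periods.  During the 120-day breeding season
(November–February) birds are colony-resident and only a conservative 10 % of
the Fe produced with guano is assumed to wash into the sea.  During the
remaining 245 days the birds forage at sea near the receding pack ice and the
totality of the produced guano — and its Fe — is taken to reach the ocean.
Production in both periods uses the same per-bird dry-guano excretion rate
and guano Fe concentration as the colony-scale budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .accumulation import GuanoParameters, guano_mass_from_census
from .quantities import InvalidInputError, UncertainQuantity

__all__ = [
    "SeasonModel",
    "GlobalPopulation",
    "AnnualBudget",
    "seasonal_fe_production",
    "annual_fe_release",
]


@dataclass(frozen=True)
class SeasonModel:
    """Two-period year with per-period Fe release efficiencies."""

    breeding_days: int = 120
    nonbreeding_days: int = 245
    breeding_release_eff: float = 0.10
    nonbreeding_release_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.breeding_days + self.nonbreeding_days != 365:
            raise InvalidInputError(
                "breeding_days + nonbreeding_days must equal 365, got "
                f"{self.breeding_days} + {self.nonbreeding_days}")
        for eff in (self.breeding_release_eff, self.nonbreeding_release_eff):
            if not 0 <= eff <= 1:
                raise InvalidInputError("release efficiencies must be in [0, 1]")


@dataclass(frozen=True)
class GlobalPopulation:
    """Global chinstrap population size.

    The default of 8 × 10⁶ individuals is the value that makes the two-period
    budget consistent with a 24.5 t Fe breeding-season release at 10 %
    efficiency under the default guano parameters
    (24.5 t / 0.10 / (84.4 g × 120 d × 3.0 mg g⁻¹) ≈ 8.06 × 10⁶, rounded to
    one significant figure of millions).
    """

    n_individuals: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(8.0e6, 0.0, "ind"))

    def __post_init__(self) -> None:
        if self.n_individuals.value < 0:
            raise InvalidInputError("population size must be >= 0")


@dataclass(frozen=True)
class AnnualBudget:
    """Per-period and total Fe release, tonnes Fe per year."""

    breeding_production: UncertainQuantity
    nonbreeding_production: UncertainQuantity
    breeding_release: UncertainQuantity
    nonbreeding_release: UncertainQuantity
    total_release: UncertainQuantity


def seasonal_fe_production(pop: GlobalPopulation, days: int,
                           params: GuanoParameters | None = None,
                           ) -> UncertainQuantity:
    """Fe produced with guano by the whole population over ``days``, tonnes.

    population × excretion rate × days × Fe concentration; the excretion rate
    is dry mass, so no dry-fraction factor enters.
    """
    if days < 0:
        raise InvalidInputError(f"days must be >= 0, got {days}")
    pool = guano_mass_from_census(pop.n_individuals, days, params)
    return pool.fe_mass.to("t")


def annual_fe_release(pop: GlobalPopulation,
                      season: SeasonModel | None = None,
                      params: GuanoParameters | None = None) -> AnnualBudget:
    """Two-period global Fe release breakdown, tonnes Fe per year.

    The release efficiency applies to Fe — equivalently to guano, since the
    Fe concentration is constant across periods.
    """
    season = season or SeasonModel()
    prod_b = seasonal_fe_production(pop, season.breeding_days, params)
    prod_nb = seasonal_fe_production(pop, season.nonbreeding_days, params)
    rel_b = prod_b * season.breeding_release_eff
    rel_nb = prod_nb * season.nonbreeding_release_eff
    return AnnualBudget(prod_b, prod_nb, rel_b, rel_nb, rel_b + rel_nb)
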