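"""Guano and iron accumulation in the colony, by two independent routes.

Volumetric route: the guano layer mapped over the guano-rich zones gives a
volume (area × layer thickness); wet density and the dry-weight fraction turn
it into dry mass, and the guano Fe concentration into an Fe mass:

    g_Fe = w · Fe · a_GRZ · t · d_guano

Individual-excretion route: the census total times a per-bird daily dry-guano
excretion rate over the residence period:

    g_Fe = Cp · Fe · e · d

The excretion rate is already a dry mass, so the dry fraction w applies only
in the volumetric route.  The two estimates are cross-checked and their mean
feeds the discharge stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .quantities import InvalidInputError, UncertainQuantity

__all__ = [
    "GuanoParameters",
    "GuanoPool",
    "guano_mass_from_volume",
    "guano_mass_from_census",
    "cross_check",
    "CrossCheck",
]


@dataclass(frozen=True)
class GuanoParameters:
    """Physical guano constants for a chinstrap colony.

    Defaults are field values for Vapour Col (Deception Island): Fe at
    3.0 ± 1.4 mg per g dry guano, a 2 cm fresh-guano layer, wet density
    1088.6 kg m⁻³, seabird dry-weight fraction 0.4, and a dry-guano excretion
    rate of 84.4 g per bird per day.
    """

    fe_conc: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(3.0, 1.4, "mg/g"))
    dry_fraction: float = 0.4
    layer_thickness: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(0.02, 0.0, "m"))
    wet_density: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(1088.6, 0.0, "kg/m3"))
    excretion_rate: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(84.4, 0.0, "g/ind/day"))

    def __post_init__(self) -> None:
        if not 0 < self.dry_fraction <= 1:
            raise InvalidInputError("dry_fraction must be in (0, 1]")
        for name in ("fe_conc", "layer_thickness", "wet_density", "excretion_rate"):
            if getattr(self, name).value <= 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class GuanoPool:
    """Accumulated guano for a zone set: volume, dry mass and Fe mass."""

    guano_volume: UncertainQuantity  # m3; zero-volume tag for the census route
    dry_mass: UncertainQuantity      # kg
    fe_mass: UncertainQuantity       # kg


def _zero_pool() -> GuanoPool:
    z = UncertainQuantity(0.0, 0.0, "kg")
    return GuanoPool(UncertainQuantity(0.0, 0.0, "m3"), z, z)


def guano_mass_from_volume(area: UncertainQuantity | None = None,
                           params: GuanoParameters | None = None,
                           *, volume: UncertainQuantity | None = None,
                           ) -> GuanoPool:
    """Volumetric guano pool from a GRZ area (or a pre-computed volume).

    ``volume = area × layer_thickness`` unless given directly;
    ``dry_mass = volume × wet_density × dry_fraction``;
    ``fe_mass = dry_mass × fe_conc``.
    """
    params = params or GuanoParameters()
    if volume is None:
        if area is None:
            raise InvalidInputError("either an area or a guano volume is required")
        if area.value < 0:
            raise InvalidInputError("area must be >= 0")
        if area.value == 0:
            return _zero_pool()
        volume = (area * params.layer_thickness).to("m3")
    elif volume.value < 0:
        raise InvalidInputError("guano volume must be >= 0")
    elif volume.value == 0:
        return _zero_pool()
    dry = (volume * params.wet_density * params.dry_fraction).to("kg")
    fe = (dry * params.fe_conc).to("kg")
    return GuanoPool(volume, dry, fe)


def guano_mass_from_census(count: UncertainQuantity, days: int,
                           params: GuanoParameters | None = None) -> GuanoPool:
    """Excretion-based guano pool: census × dry excretion rate × days.

    The excretion rate is dry mass, so no dry-fraction correction applies on
    this route.
    """
    params = params or GuanoParameters()
    if days < 0:
        raise InvalidInputError(f"days must be >= 0, got {days}")
    if count.value < 0:
        raise InvalidInputError("census count must be >= 0")
    if count.value == 0 or days == 0:
        return _zero_pool()
    per_day = count * params.excretion_rate          # g/day
    dry = (per_day * UncertainQuantity(days, 0.0, "day")).to("kg")
    fe = (dry * params.fe_conc).to("kg")
    return GuanoPool(UncertainQuantity(0.0, 0.0, "m3"), dry, fe)


@dataclass(frozen=True)
class CrossCheck:
    """Agreement report between the two accumulation routes."""

    relative_difference: float       # |a - b| / mean(a, b)
    mean_dry_mass: UncertainQuantity
    mean_fe_mass: UncertainQuantity  # the pooled value used downstream


def cross_check(pool_a: GuanoPool, pool_b: GuanoPool) -> CrossCheck:
    """Relative difference and pooled mean of two guano pools.

    The pooled Fe mean is the colony Fe stock used by the discharge stage.
    Two all-zero pools agree exactly (relative difference 0).
    """
    a = pool_a.fe_mass.to("kg")
    b = pool_b.fe_mass.to("kg")
    mean_fe = (a + b) * 0.5
    mean_dry = (pool_a.dry_mass.to("kg") + pool_b.dry_mass.to("kg")) * 0.5
    if mean_fe.value == 0:
        rel = 0.0
    else:
        rel = abs(a.value - b.value) / mean_fe.value
    return CrossCheck(rel, mean_dry, mean_fe)
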