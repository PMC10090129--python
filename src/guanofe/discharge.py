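"""Coastal water Fe inventory and colony release efficiency.

The receiving water body is modelled as a cuboid bounded by the turbidity
plume visible offshore of the colony (surface area × mean depth).  Its Fe
inventory is volume × measured Fe concentration; the release efficiency is
the fraction of the colony's accumulated guano Fe found in that inventory at
the sampling snapshot.

Uncertainty bounds on the efficiency combine the two accumulation routes by
intersecting their ±1 sd intervals: the low bound divides by the smallest
upper limit among the pools, the high bound by the largest lower limit — the
range of pool values consistent with both routes at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .quantities import (
    InvalidInputError,
    UncertainQuantity,
    UndefinedQuotientError,
)

__all__ = [
    "WaterCompartment",
    "water_fe_inventory",
    "release_efficiency",
    "efficiency_bounds",
    "UnboundedUpperError",
    "EfficiencyWarning",
]


class UnboundedUpperError(ValueError):
    """The minimising pool's value − sd is non-positive: no finite upper bound."""


class EfficiencyWarning(UserWarning):
    """Release efficiency above 1: impossible for a snapshot, flagged not fatal."""


@dataclass(frozen=True)
class WaterCompartment:
    """Near-shore cuboid under the colony's turbidity plume.

    Defaults describe the Vapour Col plume: 4 × 10⁴ m² of surface with a
    conservative 2 m mean depth (8 × 10⁴ m³) at a sampled Fe concentration of
    0.324 mg L⁻¹.
    """

    surface_area: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(4e4, 0.0, "m2"))
    mean_depth: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(2.0, 0.0, "m"))
    fe_conc: UncertainQuantity = field(
        default_factory=lambda: UncertainQuantity(0.324, 0.0, "mg/L"))

    def __post_init__(self) -> None:
        if self.surface_area.value <= 0 or self.mean_depth.value <= 0:
            raise InvalidInputError("compartment dimensions must be > 0")
        if self.fe_conc.value < 0:
            raise InvalidInputError("Fe concentration must be >= 0")

    @property
    def volume(self) -> UncertainQuantity:
        """Cuboid volume, m³."""
        return (self.surface_area * self.mean_depth).to("m3")


def water_fe_inventory(compartment: WaterCompartment) -> UncertainQuantity:
    """Fe mass dissolved in the compartment, kg.

    No seawater-density correction is applied to the mg L⁻¹ → kg conversion
    (1 m³ = 10³ L exactly).
    """
    return (compartment.volume * compartment.fe_conc).to("kg")


def release_efficiency(water_fe: UncertainQuantity,
                       pool_fe: UncertainQuantity) -> UncertainQuantity:
    """Fraction of the colony Fe pool present in the water compartment.

    Scale-invariant in its two arguments.  Values above 1 are physically
    impossible for a snapshot but can arise under sensitivity settings; they
    raise :class:`EfficiencyWarning` rather than fail.
    """
    if pool_fe.value == 0:
        raise UndefinedQuotientError("colony Fe pool is zero")
    frac = water_fe.to("kg") / pool_fe.to("kg")
    if frac.value > 1:
        warnings.warn(
            f"release efficiency {frac.value:.2f} exceeds 1 — water inventory "
            "larger than the colony pool", EfficiencyWarning, stacklevel=2)
    return frac


def efficiency_bounds(water_fe: UncertainQuantity,
                      *pools: UncertainQuantity) -> tuple[float, float]:
    """(low, high) release-efficiency bounds from pool ±1 sd intervals.

    The pools' intervals are intersected: the low bound uses the smallest
    value + sd across pools, the high bound the largest value − sd.  With a
    single pool this degenerates to (value + sd, value − sd).  All-zero sds
    collapse both bounds onto the point estimate.
    """
    if not pools:
        raise InvalidInputError("at least one Fe pool is required")
    w = water_fe.to("kg").value
    upper = min(p.to("kg").value + p.to("kg").sd for p in pools)
    lower = max(p.to("kg").value - p.to("kg").sd for p in pools)
    if lower <= 0:
        raise UnboundedUpperError(
            "pool value − sd is non-positive; the upper efficiency bound is "
            "unbounded")
    if upper <= 0:
        raise InvalidInputError("pool value + sd must be positive")
    return w / upper, w / lower
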