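"""Iron-stimulated net primary production from recycled-Fe input.

Follows the whale Fe-recycling NPP model: the released Fe mass R_Fe is
reduced by the photic-zone retention fraction p and the phytoplankton
bioavailability fraction ε and converted to moles,

    P = R_Fe · p · ε / M_Fe ,

then to fixed carbon per unit ocean area through the phytoplankton Fe:C
requirement u (µmol Fe per mol C),

    NPP = P · M_C / (u · 10⁻⁶) / a    [g C m⁻² yr⁻¹].

p and ε are each varied over min/base/max levels (0.25 / 0.5 / 0.75), moving
together by default.  All outputs are upper limits: light, macronutrient and
mixing limitations are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .quantities import (
    InvalidInputError,
    UncertainQuantity,
    UndefinedQuotientError,
)

__all__ = [
    "M_FE",
    "M_C",
    "FRACTION_LEVELS",
    "NPPScenario",
    "bioavailable_fe_mol",
    "npp_rate",
    "scenario_grid",
]

M_FE = 55.845  # g mol-1, molar mass of Fe
M_C = 12.01    # g mol-1, molar mass of C

# (min, base, max) levels shared by retention p and bioavailability ε
FRACTION_LEVELS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class NPPScenario:
    """One (R_Fe, p, ε, area) combination and its NPP upper limit."""

    r_fe: UncertainQuantity      # Fe released per year
    retention: float             # p, photic-zone retention
    bioavailability: float       # ε
    area: UncertainQuantity      # m2
    fe_c_ratio: float = 3.0      # u, µmol Fe per mol C
    label: str = ""

    @property
    def npp(self) -> UncertainQuantity:
        """g C m⁻² yr⁻¹ (upper limit)."""
        p_mol = bioavailable_fe_mol(self.r_fe, self.retention,
                                    self.bioavailability)
        return npp_rate(p_mol, self.fe_c_ratio, self.area)


def _check_fraction(name: str, x: float) -> None:
    if not 0 < x <= 1:
        raise InvalidInputError(f"{name} must be in (0, 1], got {x}")


def bioavailable_fe_mol(r_fe: UncertainQuantity, retention: float,
                        bioavailability: float) -> UncertainQuantity:
    """Moles of Fe available to phytoplankton: R_Fe · p · ε / M_Fe."""
    _check_fraction("retention", retention)
    _check_fraction("bioavailability", bioavailability)
    grams = r_fe.to("g")
    mol = grams.value * retention * bioavailability / M_FE
    return UncertainQuantity(mol, mol * grams.rel_sd, "mol")


def npp_rate(p_mol: UncertainQuantity, fe_c_ratio: float,
             area: UncertainQuantity) -> UncertainQuantity:
    """NPP from bioavailable Fe: P / (u·10⁻⁶) · M_C / a, g C m⁻² yr⁻¹.

    ``p_mol`` is the Fe made bioavailable over one year, so the result is an
    annual rate; the yr⁻¹ tag is attached to the output unit accordingly.
    """
    if fe_c_ratio <= 0:
        raise InvalidInputError("Fe:C ratio must be > 0")
    if area.value == 0:
        raise UndefinedQuotientError("ocean area is zero")
    mol_c = p_mol.to("mol") / (fe_c_ratio * 1e-6)
    grams_c = mol_c * UncertainQuantity(M_C, 0.0, "g/mol")
    per_area = (grams_c / area.to("m2")).to("g/m2")
    return UncertainQuantity(per_area.value, per_area.sd, "g/m2/yr")


def scenario_grid(r_fe: UncertainQuantity,
                  areas: dict[str, UncertainQuantity] | Sequence[UncertainQuantity],
                  fraction_levels: Iterable[float] = FRACTION_LEVELS,
                  fe_c_ratio: float = 3.0,
                  full_cross: bool = False) -> pd.DataFrame:
    """NPP scenario table over bioavailability levels and ocean areas.

    One row per (level, area) with p = ε = level — three scenario outputs per
    area, p·ε ∈ {0.0625, 0.25, 0.5625} at the default levels.  With
    ``full_cross=True`` the independent p × ε grid is produced instead.
    Columns: label, area_m2, p, epsilon, npp_g_c_m2_yr, npp_sd, note.
    """
    levels = sorted(fraction_levels)
    if not levels:
        raise InvalidInputError("at least one fraction level is required")
    if isinstance(areas, dict):
        named = list(areas.items())
    else:
        named = [(f"area_{i}", a) for i, a in enumerate(areas)]
    if not named:
        raise InvalidInputError("at least one area is required")
    pairs = ([(p, e) for p in levels for e in levels] if full_cross
             else [(lv, lv) for lv in levels])
    rows = []
    for label, area in named:
        for p, eps in pairs:
            s = NPPScenario(r_fe, p, eps, area, fe_c_ratio, label)
            rows.append({
                "label": label,
                "area_m2": area.to("m2").value,
                "p": p,
                "epsilon": eps,
                "npp_g_c_m2_yr": s.npp.value,
                "npp_sd": s.npp.sd,
                "note": "upper limit",
            })
    return pd.DataFrame(rows)
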