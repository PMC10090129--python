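"""Uncertain physical quantities with exact-rational units.

Every number that flows through the iron-budget pipeline — guano masses,
penguin counts, Fe concentrations, water volumes — is an
:class:`UncertainQuantity`: a non-negative value, a standard deviation and a
unit tag.  Two propagation rules are provided for pure products/quotients of
independent factors:

* first-order (delta-method): relative variances add;
* Monte-Carlo: each factor drawn from a normal truncated at zero, so that
  masses and concentrations can never go negative.

Unit conversion factors are exact rationals (1 t = 10^3 kg = 10^6 g,
1 m^3 = 10^3 L), so round-trip conversions are identities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "UncertainQuantity",
    "propagate_first_order",
    "propagate_monte_carlo",
    "round_report",
    "UndefinedQuotientError",
    "InvalidConfigurationError",
    "InvalidInputError",
    "UnitError",
    "DEFAULT_DRAWS",
    "DEFAULT_SEED",
]

# Defaults for Monte-Carlo propagation; the seed encodes a fixed date so runs
# are reproducible out of the box while remaining configurable everywhere.
DEFAULT_DRAWS = 100_000
DEFAULT_SEED = 20230411


class UnitError(ValueError):
    """Unknown unit symbol or incompatible dimensions in a conversion."""


class UndefinedQuotientError(ZeroDivisionError):
    """Division by a quantity whose value is zero."""


class InvalidConfigurationError(ValueError):
    """A propagation or simulation configuration that cannot be run."""


class InvalidInputError(ValueError):
    """A physical input outside its valid domain (negative mass, area...)."""


# --------------------------------------------------------------------------
# Units: dimension vector over (mass[kg], length[m], individuals, mol, time[day])
# with an exact rational scale relative to the coherent base unit.
# --------------------------------------------------------------------------

_BASE = ("kg", "m", "ind", "mol", "day")
_DimVec = tuple[int, int, int, int, int]


@dataclass(frozen=True)
class _Unit:
    scale: Fraction
    dims: _DimVec

    def __mul__(self, other: "_Unit") -> "_Unit":
        return _Unit(self.scale * other.scale,
                     tuple(a + b for a, b in zip(self.dims, other.dims)))

    def __truediv__(self, other: "_Unit") -> "_Unit":
        return _Unit(self.scale / other.scale,
                     tuple(a - b for a, b in zip(self.dims, other.dims)))

    def __pow__(self, n: int) -> "_Unit":
        return _Unit(self.scale ** n, tuple(a * n for a in self.dims))


def _d(kg=0, m=0, ind=0, mol=0, day=0) -> _DimVec:
    return (kg, m, ind, mol, day)


_ATOMS: dict[str, _Unit] = {
    "": _Unit(Fraction(1), _d()),
    "1": _Unit(Fraction(1), _d()),
    "kg": _Unit(Fraction(1), _d(kg=1)),
    "g": _Unit(Fraction(1, 10**3), _d(kg=1)),
    "mg": _Unit(Fraction(1, 10**6), _d(kg=1)),
    "ug": _Unit(Fraction(1, 10**9), _d(kg=1)),
    "t": _Unit(Fraction(10**3), _d(kg=1)),
    "m": _Unit(Fraction(1), _d(m=1)),
    "m2": _Unit(Fraction(1), _d(m=2)),
    "m3": _Unit(Fraction(1), _d(m=3)),
    "L": _Unit(Fraction(1, 10**3), _d(m=3)),
    "ind": _Unit(Fraction(1), _d(ind=1)),
    "mol": _Unit(Fraction(1), _d(mol=1)),
    "umol": _Unit(Fraction(1, 10**6), _d(mol=1)),
    "day": _Unit(Fraction(1), _d(day=1)),
    "yr": _Unit(Fraction(365), _d(day=1)),
}

# Preferred names for derived-unit results, looked up by (scale, dims).
_PREFERRED = [
    "1", "kg", "g", "mg", "t", "m", "m2", "m3", "L", "ind", "mol", "day", "yr",
    "mg/g", "mg/L", "kg/m3", "ind/m2", "g/mol", "g/ind/day", "t/yr",
    "g/m2", "g/m2/yr", "umol/mol", "kg/day", "g/day", "t/day",
]


def parse_unit(symbol: str) -> _Unit:
    """Resolve a unit string like ``"mg/g"`` or ``"g/ind/day"``.

    The grammar is a product of atoms separated by ``*`` with any number of
    trailing ``/atom`` divisors; exponents are spelled into the atom itself
    (``m2``, ``m3``).
    """
    sym = symbol.strip()
    parts = sym.split("/")
    try:
        unit = _ATOMS[""]
        for token in parts[0].split("*"):
            unit = unit * _ATOMS[token.strip()]
        for part in parts[1:]:
            unit = unit / _ATOMS[part.strip()]
    except KeyError as exc:
        raise UnitError(f"unknown unit symbol {exc.args[0]!r} in {symbol!r}") from exc
    return unit


_BY_VALUE: dict[tuple[Fraction, _DimVec], str] = {}
for _name in reversed(_PREFERRED):
    _u = parse_unit(_name)
    _BY_VALUE[(_u.scale, _u.dims)] = _name


def _name_unit(unit: _Unit) -> tuple[str, Fraction]:
    """Best display name for a derived unit and the factor into that name.

    Falls back to the coherent base combination (scale folded into the value)
    when no preferred symbol matches exactly.
    """
    key = (unit.scale, unit.dims)
    if key in _BY_VALUE:
        return _BY_VALUE[key], Fraction(1)
    base = _Unit(Fraction(1), unit.dims)
    if (base.scale, base.dims) in _BY_VALUE:
        return _BY_VALUE[(base.scale, base.dims)], unit.scale
    num = "*".join(f"{b}{'' if e == 1 else e}" for b, e in zip(_BASE, unit.dims) if e > 0)
    den = "/".join(f"{b}{'' if e == -1 else -e}" for b, e in zip(_BASE, unit.dims) if e < 0)
    name = (num or "1") + (f"/{den}" if den else "")
    return name, unit.scale


# --------------------------------------------------------------------------
# UncertainQuantity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainQuantity:
    """A value ± standard deviation carrying a unit tag.

    ``sd = 0`` denotes an exact quantity. Arithmetic between quantities uses
    the independent-factor first-order rule for ``*`` and ``/`` and quadrature
    for ``+`` and ``-``.
    """

    value: float
    sd: float = 0.0
    unit: str = "1"
    _resolved: _Unit = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidInputError(f"standard deviation must be >= 0, got {self.sd}")
        # exact rational conversion factors may arrive as Fraction; values stay float
        object.__setattr__(self, "value", float(self.value))
        object.__setattr__(self, "sd", float(self.sd))
        object.__setattr__(self, "_resolved", parse_unit(self.unit))

    # -- conversions -------------------------------------------------------
    def to(self, unit: str) -> "UncertainQuantity":
        """Convert to another unit of the same dimension (exact factor)."""
        target = parse_unit(unit)
        if target.dims != self._resolved.dims:
            raise UnitError(f"cannot convert {self.unit!r} to {unit!r}: "
                            "incompatible dimensions")
        factor = self._resolved.scale / target.scale
        return UncertainQuantity(self.value * factor, self.sd * factor, unit)

    @property
    def rel_sd(self) -> float:
        """Relative standard deviation; zero for an exactly-zero quantity."""
        return 0.0 if self.value == 0 else self.sd / abs(self.value)

    # -- arithmetic --------------------------------------------------------
    def _combine(self, other: "UncertainQuantity", unit: _Unit,
                 value: float) -> "UncertainQuantity":
        rel = math.hypot(self.rel_sd, other.rel_sd)
        name, fold = _name_unit(unit)
        v = value * fold
        return UncertainQuantity(v, abs(v) * rel, name)

    def __mul__(self, other):
        if isinstance(other, UncertainQuantity):
            return self._combine(other, self._resolved * other._resolved,
                                 self.value * other.value)
        name, fold = _name_unit(self._resolved)
        return UncertainQuantity(self.value * other * fold,
                                 self.sd * abs(other) * fold, name)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, UncertainQuantity):
            if other.value == 0:
                raise UndefinedQuotientError("division by a zero-valued quantity")
            return self._combine(other, self._resolved / other._resolved,
                                 self.value / other.value)
        if other == 0:
            raise UndefinedQuotientError("division by zero")
        return self * (1.0 / other)

    def _add_like(self, other: "UncertainQuantity", sign: int) -> "UncertainQuantity":
        o = other.to(self.unit)
        return UncertainQuantity(self.value + sign * o.value,
                                 math.hypot(self.sd, o.sd), self.unit)

    def __add__(self, other: "UncertainQuantity") -> "UncertainQuantity":
        return self._add_like(other, +1)

    def __sub__(self, other: "UncertainQuantity") -> "UncertainQuantity":
        return self._add_like(other, -1)

    def __str__(self) -> str:
        u = "" if self.unit in ("", "1") else f" {self.unit}"
        return f"{self.value:g} ± {self.sd:g}{u}"


# --------------------------------------------------------------------------
# Propagation
# --------------------------------------------------------------------------

def _check_exponents(factors: Sequence[UncertainQuantity],
                     exponents: Sequence[int] | None) -> list[int]:
    if exponents is None:
        return [1] * len(factors)
    if len(exponents) != len(factors):
        raise InvalidConfigurationError("one exponent per factor required")
    return list(exponents)


def propagate_first_order(factors: Sequence[UncertainQuantity],
                          exponents: Sequence[int] | None = None,
                          unit: str | None = None) -> UncertainQuantity:
    """Delta-method propagation through a product/quotient of factors.

    ``exponents`` (default all +1) gives the power of each factor; -1 divides.
    The result value is ``prod(v_i ** e_i)`` and the relative variance is
    ``sum(e_i**2 * (sd_i / v_i)**2)`` — the independent-factor first-order
    rule.  ``unit`` optionally converts the result.
    """
    exps = _check_exponents(factors, exponents)
    res_unit = _ATOMS["1"]
    value = 1.0
    relvar = 0.0
    for f, e in zip(factors, exps):
        if e < 0 and f.value == 0:
            raise UndefinedQuotientError("quotient by a zero-valued factor")
        value *= f.value ** e
        relvar += (e * f.rel_sd) ** 2
        res_unit = res_unit * (f._resolved ** e)
    name, fold = _name_unit(res_unit)
    v = value * fold
    out = UncertainQuantity(v, abs(v) * math.sqrt(relvar), name)
    return out.to(unit) if unit is not None else out


def propagate_monte_carlo(factors: Sequence[UncertainQuantity],
                          exponents: Sequence[int] | None = None,
                          draws: int = DEFAULT_DRAWS,
                          seed: int = DEFAULT_SEED,
                          unit: str | None = None) -> UncertainQuantity:
    """Monte-Carlo propagation with zero-truncated normal sampling.

    Each factor is drawn from a normal ``N(value, sd)`` truncated at zero
    (physical quantities here cannot be negative); the returned quantity holds
    the sample mean and sample standard deviation of the product. Reproducible
    for a fixed ``seed``. Truncation biases the mean high by roughly
    ``rel_sd * phi(1/rel_sd)`` per factor, negligible below ~20 % relative sd.
    """
    if draws <= 0:
        raise InvalidConfigurationError(f"draws must be positive, got {draws}")
    exps = _check_exponents(factors, exponents)
    rng = np.random.default_rng(seed)
    sample = np.ones(draws)
    res_unit = _ATOMS["1"]
    for f, e in zip(factors, exps):
        if f.sd == 0:
            x = np.full(draws, f.value)
        else:
            a = (0.0 - f.value) / f.sd
            x = stats.truncnorm.rvs(a, np.inf, loc=f.value, scale=f.sd,
                                    size=draws, random_state=rng)
        if e < 0 and np.any(x == 0):
            raise UndefinedQuotientError("quotient by a zero-valued draw")
        sample = sample * x ** e
        res_unit = res_unit * (f._resolved ** e)
    name, fold = _name_unit(res_unit)
    fold = float(fold)
    out = UncertainQuantity(float(sample.mean()) * fold,
                            float(sample.std(ddof=1)) * fold if draws > 1 else 0.0,
                            name)
    return out.to(unit) if unit is not None else out


def round_report(value: float, ndigits: int = 0) -> float:
    """Half-away-from-zero rounding used for report output.

    Internal computation stays at full precision; only printed numbers are
    rounded, to the precision the quantity is conventionally reported at.
    """
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * q + 0.5) / q, value)
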