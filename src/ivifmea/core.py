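"""Interval-valued intuitionistic fuzzy numbers and their algebra.

An interval-valued intuitionistic fuzzy (IVIF) number assigns to a statement a
membership *interval* [mu_lo, mu_hi] and a non-membership interval
[nu_lo, nu_hi], with mu_hi + nu_hi <= 1.  The belief that is committed to
neither side is the hesitation interval

    pi = [1 - mu_hi - nu_hi,  1 - mu_lo - nu_lo].

Throughout the package an IVIF number is written ``(a, b; c, d)`` with
a = mu_lo, b = mu_hi, c = nu_lo, d = nu_hi.

The algebraic operations follow the standard Atanassov/Xu operational laws:
addition is the probabilistic-sum t-conorm on membership and the product
t-norm on non-membership, multiplication is its dual, and scalar
multiplication / exponentiation are their limit forms.  All four operations
are closed on valid IVIF numbers, addition and multiplication commute, and
scalar multiplication distributes over addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IVIFNumber",
    "IVIFValidationError",
    "add",
    "complement",
    "hesitation",
    "multiply",
    "power",
    "scale",
]

#: Absolute slack used when validating invariants, to absorb float round-off.
VALIDATION_TOL = 1e-9

#: Slack for the mu_hi + nu_hi <= 1 consistency check only.  Report data
#: rounded to 3 decimals can overshoot the sum by up to one rounding unit
#: (5e-4 per component); such quadruples are accepted as exact.
SUM_TOL = 1.0e-3 + 1e-9


class IVIFValidationError(ValueError):
    """Raised when a quadruple violates an IVIF invariant."""


@dataclass(frozen=True)
class IVIFNumber:
    """An IVIF number ``(a, b; c, d)``.

    Parameters
    ----------
    mu_lo, mu_hi:
        Lower and upper membership bounds, ``0 <= mu_lo <= mu_hi <= 1``.
    nu_lo, nu_hi:
        Lower and upper non-membership bounds, ``0 <= nu_lo <= nu_hi <= 1``,
        with ``mu_hi + nu_hi <= 1``.
    """

    mu_lo: float
    mu_hi: float
    nu_lo: float
    nu_hi: float

    def __post_init__(self) -> None:
        a, b, c, d = self.mu_lo, self.mu_hi, self.nu_lo, self.nu_hi
        t = VALIDATION_TOL
        for name, v in (("mu_lo", a), ("mu_hi", b), ("nu_lo", c), ("nu_hi", d)):
            if not (-t <= v <= 1 + t):
                raise IVIFValidationError(
                    f"{name}={v!r} outside [0, 1] in ({a}, {b}; {c}, {d})"
                )
        if a > b + t:
            raise IVIFValidationError(
                f"membership interval inverted: mu_lo={a} > mu_hi={b}"
            )
        if c > d + t:
            raise IVIFValidationError(
                f"non-membership interval inverted: nu_lo={c} > nu_hi={d}"
            )
        if b + d > 1 + SUM_TOL:
            raise IVIFValidationError(
                f"mu_hi + nu_hi = {b + d} > 1 in ({a}, {b}; {c}, {d})"
            )

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_sequence(cls, seq: Sequence[float]) -> "IVIFNumber":
        """Build from an ordered 4-sequence ``[mu_lo, mu_hi, nu_lo, nu_hi]``."""
        a, b, c, d = seq
        return cls(float(a), float(b), float(c), float(d))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mu_lo, self.mu_hi, self.nu_lo, self.nu_hi)

    def as_list(self) -> list[float]:
        """JSON form: the ordered 4-list ``[mu_lo, mu_hi, nu_lo, nu_hi]``."""
        return [self.mu_lo, self.mu_hi, self.nu_lo, self.nu_hi]

    def __str__(self) -> str:  # report notation "(a, b; c, d)"
        return (
            f"({self.mu_lo:g}, {self.mu_hi:g}; {self.nu_lo:g}, {self.nu_hi:g})"
        )

    def round(self, ndigits: int = 3) -> "IVIFNumber":
        """Component-wise rounding, for report output only."""
        return IVIFNumber(*(round(v, ndigits) for v in self.as_tuple()))

    # -- derived quantities ----------------------------------------------

    @property
    def hesitation(self) -> tuple[float, float]:
        """Hesitation interval ``[1 - mu_hi - nu_hi, 1 - mu_lo - nu_lo]``.

        Clamped at 0 so that fixture values rounded to 3 decimals cannot
        produce a spurious -1e-3 lower bound.
        """
        lo = max(0.0, 1.0 - self.mu_hi - self.nu_hi)
        hi = max(0.0, 1.0 - self.mu_lo - self.nu_lo)
        return (lo, max(lo, hi))

    # -- algebra ----------------------------------------------------------

    def complement(self) -> "IVIFNumber":
        """Swap membership and non-membership: ``(c, d; a, b)``."""
        return IVIFNumber(self.nu_lo, self.nu_hi, self.mu_lo, self.mu_hi)

    def __add__(self, other: "IVIFNumber") -> "IVIFNumber":
        a1, b1, c1, d1 = self.as_tuple()
        a2, b2, c2, d2 = other.as_tuple()
        return IVIFNumber(
            a1 + a2 - a1 * a2,
            b1 + b2 - b1 * b2,
            c1 * c2,
            d1 * d2,
        )

    def __mul__(self, other: "IVIFNumber") -> "IVIFNumber":
        a1, b1, c1, d1 = self.as_tuple()
        a2, b2, c2, d2 = other.as_tuple()
        return IVIFNumber(
            a1 * a2,
            b1 * b2,
            c1 + c2 - c1 * c2,
            d1 + d2 - d1 * d2,
        )

    def scale(self, lam: float) -> "IVIFNumber":
        """Scalar multiple ``lam * x`` for ``lam > 0``.

        ``(1-(1-a)^lam, 1-(1-b)^lam; c^lam, d^lam)``.
        """
        if not lam > 0:
            raise ValueError(f"scalar multiplier must be positive, got {lam}")
        a, b, c, d = self.as_tuple()
        return IVIFNumber(
            1.0 - (1.0 - a) ** lam,
            1.0 - (1.0 - b) ** lam,
            c**lam,
            d**lam,
        )

    def power(self, lam: float) -> "IVIFNumber":
        """Exponentiation ``x ** lam`` for ``lam > 0``, the dual of :meth:`scale`.

        ``(a^lam, b^lam; 1-(1-c)^lam, 1-(1-d)^lam)``.  ``0**lam`` is 0 for
        ``lam > 0``, so a zero membership bound stays zero under any positive
        exponent.  This is the unique dual choice satisfying
        ``power(complement(x), lam) == complement(scale(lam, x))``.
        """
        if not lam > 0:
            raise ValueError(f"exponent must be positive, got {lam}")
        a, b, c, d = self.as_tuple()
        return IVIFNumber(
            a**lam,
            b**lam,
            1.0 - (1.0 - c) ** lam,
            1.0 - (1.0 - d) ** lam,
        )

    def __pow__(self, lam: float) -> "IVIFNumber":
        return self.power(lam)

    def isclose(self, other: "IVIFNumber", abs_tol: float = 1e-12) -> bool:
        return all(
            math.isclose(u, v, rel_tol=0.0, abs_tol=abs_tol)
            for u, v in zip(self.as_tuple(), other.as_tuple())
        )


# -- functional aliases ---------------------------------------------------
# The operator algebra is also exposed as module-level functions, which read
# more naturally in aggregation formulas.


def complement(x: IVIFNumber) -> IVIFNumber:
    return x.complement()


def add(x: IVIFNumber, y: IVIFNumber) -> IVIFNumber:
    return x + y


def multiply(x: IVIFNumber, y: IVIFNumber) -> IVIFNumber:
    return x * y


def scale(lam: float, x: IVIFNumber) -> IVIFNumber:
    return x.scale(lam)


def power(x: IVIFNumber, lam: float) -> IVIFNumber:
    return x.power(lam)


def hesitation(x: IVIFNumber) -> tuple[float, float]:
    return x.hesitation


def product(values: Iterable[IVIFNumber]) -> IVIFNumber:
    """IVIF product of an iterable (at least one element)."""
    it = iter(values)
    try:
        out = next(it)
    except StopIteration:
        raise ValueError("product of an empty IVIF sequence") from None
    for v in it:
        out = out * v
    return out
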