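"""Weighted fuzzy risk-priority numbers and GIS importance scores.

The classical FMEA risk-priority number RPN = S x O x D ignores attribute
weights; the weighted form RPN = S^wS x O^wO x D^wD does not.  Here the
three attributes are severity, preventability (playing detectability's
role) and occurrence, each an aggregated IVIF number, and the weighted RPN
is evaluated in the IVIF algebra: each attribute is raised to its weight
with the power operator and the results are IVIF-multiplied.

Two variants matter downstream:

ideal RPN
    the same product with occurrence pinned to the best possible level,
    "Rare" = (0, 0.2; 0.5, 0.8).  Because Rare's membership lower bound is
    0, every ideal RPN has mu_lo = 0.

importance RPN
    the occurrence-free product over severity and preventability only, with
    the two remaining weights renormalized to sum to 1.  Used to rank errors
    that have no occurrence data at all.

The generalized improved score (GIS) maps an IVIF number (a, b; c, d) to

    GIS = (a + b)/2 + k1 * a * (1 - a - c) + k2 * b * (1 - b - d)

with attitude parameters k1 + k2 = 1, k1, k2 >= 0 weighting the membership
and non-membership hesitation contributions.  Note that GIS can slightly
exceed 1 for valid low-hesitation inputs (e.g. (0.8, 1; 0, 0) at k1 = 1
scores 1.06), so the score is not clamped or asserted to [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import IVIFNumber, multiply, power
from .scales import builtin_scales

__all__ = [
    "AttributeWeights",
    "GISParameters",
    "ImportanceReport",
    "MissingOccurrenceError",
    "RiskProfile",
    "crisp_rpn",
    "DEFAULT_K1_GRID",
    "fuzzy_rpn",
    "gis",
    "ideal_rpn",
    "importance_rpn",
    "importance_table",
    "rare_term",
]

#: k1 grid used by default in importance reports.
DEFAULT_K1_GRID: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


class MissingOccurrenceError(ValueError):
    """Raised when an occurrence-dependent score is requested for a profile
    without occurrence data; use the importance-score path instead."""


@dataclass(frozen=True)
class AttributeWeights:
    """Positive attribute weights for severity / preventability / occurrence.

    The defaults (0.387, 0.334, 0.279) are the survey-derived weights used
    in the bundled case study; they sum to 1.
    """

    severity: float = 0.387
    preventability: float = 0.334
    occurrence: float = 0.279

    def __post_init__(self) -> None:
        for name in ("severity", "preventability", "occurrence"):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"attribute weight {name} must be positive, "
                    f"got {getattr(self, name)}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "AttributeWeights":
        payload = json.loads(Path(path).read_text())
        return cls(
            severity=payload["severity"],
            preventability=payload["preventability"],
            occurrence=payload["occurrence"],
        )

    def renormalized_sp(self) -> tuple[float, float]:
        """Severity/preventability weights rescaled to sum to 1 (the
        occurrence-free importance path)."""
        total = self.severity + self.preventability
        return self.severity / total, self.preventability / total


@dataclass(frozen=True)
class RiskProfile:
    """Aggregated attribute IVIFs for one error.

    Occurrence may be absent; such profiles can only travel the
    importance-score path.
    """

    error_code: str
    severity: IVIFNumber
    preventability: IVIFNumber
    occurrence: IVIFNumber | None = None
    error_name: str = ""
    category: str = ""


@dataclass(frozen=True)
class GISParameters:
    """Hesitancy-attitude weights, k1 + k2 = 1, both nonnegative."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError(f"k1, k2 must be nonnegative: ({self.k1}, {self.k2})")
        if abs(self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError(
                f"k1 + k2 must equal 1, got {self.k1} + {self.k2}"
            )


def rare_term() -> IVIFNumber:
    """The best-case occurrence level, Rare = (0, 0.2; 0.5, 0.8)."""
    return builtin_scales()["occurrence"].lookup("Rare")


def crisp_rpn(
    s: int, o: int, d: int, weights: AttributeWeights | None = None
) -> float:
    """Classical crisp RPN on 1-10 ratings.

    Unweighted product S*O*D when ``weights`` is None, else the weighted
    power product S^wS * O^wO * D^wD.  Provided as the conventional
    baseline for comparison output.
    """
    for name, v in (("severity", s), ("occurrence", o), ("detectability", d)):
        if not (isinstance(v, (int,)) and 1 <= v <= 10):
            raise ValueError(f"{name} rating must be an integer in 1..10, got {v!r}")
    if weights is None:
        return float(s * o * d)
    return math.exp(
        weights.severity * math.log(s)
        + weights.occurrence * math.log(o)
        + weights.preventability * math.log(d)
    )


def fuzzy_rpn(profile: RiskProfile, weights: AttributeWeights) -> IVIFNumber:
    """Weighted IVIF risk-priority number S^wS * P^wP * O^wO.

    Order-independent because IVIF multiplication commutes.
    """
    if profile.occurrence is None:
        raise MissingOccurrenceError(
            f"error {profile.error_code!r} has no occurrence data; "
            "use importance_rpn for the occurrence-free ranking"
        )
    return multiply(
        multiply(
            power(profile.severity, weights.severity),
            power(profile.preventability, weights.preventability),
        ),
        power(profile.occurrence, weights.occurrence),
    )


def ideal_rpn(profile: RiskProfile, weights: AttributeWeights) -> IVIFNumber:
    """The weighted RPN with occurrence pinned to "Rare".

    This is the per-error best case the index score compares against; its
    membership lower bound is always 0 because Rare's is.
    """
    return multiply(
        multiply(
            power(profile.severity, weights.severity),
            power(profile.preventability, weights.preventability),
        ),
        power(rare_term(), weights.occurrence),
    )


def importance_rpn(
    profile: RiskProfile, weights: AttributeWeights
) -> IVIFNumber:
    """Occurrence-free weighted RPN over severity and preventability.

    The two remaining weights are renormalized to sum to 1, so a profile
    with identical severity and preventability maps to itself.
    """
    w_s, w_p = weights.renormalized_sp()
    return multiply(
        power(profile.severity, w_s), power(profile.preventability, w_p)
    )


def gis(x: IVIFNumber, params: GISParameters | float) -> float:
    """Generalized improved score of an IVIF number.

    ``params`` is either a :class:`GISParameters` or a bare k1 (k2 = 1-k1).
    """
    if not isinstance(params, GISParameters):
        params = GISParameters(k1=float(params), k2=1.0 - float(params))
    a, b, c, d = x.as_tuple()
    return (
        (a + b) / 2.0
        + params.k1 * a * (1.0 - a - c)
        + params.k2 * b * (1.0 - b - d)
    )


@dataclass(frozen=True)
class ImportanceReport:
    """Importance scores and ranks per k1, plus a rank-stability flag.

    ``table`` is indexed by error_code with columns ``score_k{k1}`` and
    ``rank_k{k1}`` for each grid value; ``stable`` is True when the ranking
    is identical in every column.
    """

    table: pd.DataFrame
    k1_grid: tuple[float, ...]
    stable: bool


def importance_table(
    profiles: Sequence[RiskProfile],
    weights: AttributeWeights,
    k1_grid: Sequence[float] = DEFAULT_K1_GRID,
) -> ImportanceReport:
    """GIS importance scores for each error across a k1 grid.

    For each k1 (k2 = 1 - k1), every error's importance RPN is scored with
    GIS and ranked descending (rank 1 = highest score = most important).
    Ties break by error_code, lexicographically and stably.
    """
    k1_grid = tuple(float(k) for k in k1_grid)
    for k in k1_grid:
        if not 0.0 <= k <= 1.0:
            raise ValueError(f"k1 grid values must lie in [0, 1], got {k}")
    codes = [p.error_code for p in profiles]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate error codes in profiles")
    rpns = {p.error_code: importance_rpn(p, weights) for p in profiles}
    table = pd.DataFrame(index=pd.Index(codes, name="error_code"))
    rank_columns = []
    for k1 in k1_grid:
        scores = {code: gis(rpns[code], k1) for code in codes}
        order = sorted(codes, key=lambda c: (-scores[c], c))
        ranks = {c: i + 1 for i, c in enumerate(order)}
        table[f"score_k{k1:g}"] = [scores[c] for c in codes]
        table[f"rank_k{k1:g}"] = [ranks[c] for c in codes]
        rank_columns.append(tuple(ranks[c] for c in codes))
    stable = all(col == rank_columns[0] for col in rank_columns[1:])
    return ImportanceReport(table=table, k1_grid=k1_grid, stable=stable)
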