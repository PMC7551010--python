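"""IVIF similarity via the median operator and an entropy measure.

The index score of an error is the similarity between its weighted RPN and
its ideal ("Rare"-occurrence) RPN.  Similarity is defined through a median
operator M(A, B), an IVIF number built from the four quantities

    M1 = [2 + |du-| + |dv-| - (piA+ + piB+)] / 4
    M2 = [2 + |du+| + |dv+| - (piA- + piB-)] / 4
    M3 = [2 - |du-| + |dv-| - (piA+ + piB+)] / 4
    M4 = [2 - |du+| + |dv+| - (piA- + piB-)] / 4

(du, dv are the membership / non-membership bound differences of A and B,
pi their hesitation bounds) with membership interval [min, max](M1, M2) and
non-membership interval [min, max](M3, M4).  The similarity is the entropy
of M(A, B), which collapses to the closed form

    S(A, B) = [4 - D + P] / [4 + D + P],
    D = |du-| + |du+| + |dv-| + |dv+|,
    P = piA- + piB- + piA+ + piB+.

S is symmetric, equals 1 exactly when A = B, and lies in [0, 1].  High
hesitation drives S toward 1: two vague assessments are hard to tell apart.
The direct ratio form is the definition used for scoring; the
entropy-of-median route coincides with it exactly whenever the pair shares
its non-membership interval (dv- = dv+ = 0, the regime of the defining
worked example) and deviates by the sign of the dv terms in the
denominator otherwise.

Errors are ranked by ascending index score: the *least* similar to its own
ideal case is the furthest from "rarely happens" and gets priority rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .core import IVIFNumber
from .scoring import AttributeWeights, RiskProfile, fuzzy_rpn, ideal_rpn

__all__ = [
    "IndexRow",
    "RankComparison",
    "compare_rankings",
    "element_similarity",
    "entropy",
    "index_table",
    "median_operator",
    "similarity",
]


def _pair_terms(a: IVIFNumber, b: IVIFNumber):
    du_lo = abs(a.mu_lo - b.mu_lo)
    du_hi = abs(a.mu_hi - b.mu_hi)
    dv_lo = abs(a.nu_lo - b.nu_lo)
    dv_hi = abs(a.nu_hi - b.nu_hi)
    pa_lo, pa_hi = a.hesitation
    pb_lo, pb_hi = b.hesitation
    return du_lo, du_hi, dv_lo, dv_hi, pa_lo + pb_lo, pa_hi + pb_hi


def median_operator(a: IVIFNumber, b: IVIFNumber) -> IVIFNumber:
    """The median IVIF number M(A, B) of a pair."""
    du_lo, du_hi, dv_lo, dv_hi, pi_lo, pi_hi = _pair_terms(a, b)
    m1 = (2.0 + du_lo + dv_lo - pi_hi) / 4.0
    m2 = (2.0 + du_hi + dv_hi - pi_lo) / 4.0
    m3 = (2.0 - du_lo + dv_lo - pi_hi) / 4.0
    m4 = (2.0 - du_hi + dv_hi - pi_lo) / 4.0
    try:
        return IVIFNumber(
            min(m1, m2), max(m1, m2), min(m3, m4), max(m3, m4)
        )
    except ValueError as exc:
        raise ValueError(
            f"median operator produced an invalid IVIF number for "
            f"{a} and {b}: {exc}"
        ) from exc


def entropy(x: IVIFNumber) -> float:
    """Entropy of an IVIF number: 1 for total vagueness, smaller the more
    decisively membership and non-membership separate."""
    pi_lo, pi_hi = x.hesitation
    sep = abs(x.mu_lo - x.nu_lo) + abs(x.mu_hi - x.nu_hi)
    return (2.0 - sep + pi_lo + pi_hi) / (2.0 + sep + pi_lo + pi_hi)


def similarity(a: IVIFNumber, b: IVIFNumber) -> float:
    """Similarity S(A, B) in [0, 1].

    Equals ``entropy(median_operator(a, b))`` whenever a and b share their
    non-membership interval; see the module docstring.
    """
    du_lo, du_hi, dv_lo, dv_hi, pi_lo, pi_hi = _pair_terms(a, b)
    diff = du_lo + du_hi + dv_lo + dv_hi
    pi = pi_lo + pi_hi
    return (4.0 - diff + pi) / (4.0 + diff + pi)


def element_similarity(
    pairs: Sequence[tuple[IVIFNumber, IVIFNumber]]
) -> float:
    """Mean per-element similarity over a sequence of (A, B) pairs."""
    if not pairs:
        raise ValueError("element_similarity of an empty pair list")
    return sum(similarity(a, b) for a, b in pairs) / len(pairs)


@dataclass(frozen=True)
class IndexRow:
    """One error's row of the index report."""

    error_code: str
    rpn: IVIFNumber
    ideal: IVIFNumber
    index_score: float
    rank: int


def index_table(
    profiles: Sequence[RiskProfile], weights: AttributeWeights
) -> list[IndexRow]:
    """Index scores and priority ranks for errors with occurrence data.

    Per error: RPN, ideal RPN, index score = similarity(RPN, ideal).  Rank 1
    is the smallest index score (least similar to its ideal case, hence the
    highest remediation priority); ties break by error_code.
    """
    rows = []
    for p in profiles:
        rpn = fuzzy_rpn(p, weights)  # raises MissingOccurrenceError if needed
        ideal = ideal_rpn(p, weights)
        rows.append((p.error_code, rpn, ideal, similarity(rpn, ideal)))
    order = sorted(rows, key=lambda r: (r[3], r[0]))
    ranks = {code: i + 1 for i, (code, *_rest) in enumerate(order)}
    return [
        IndexRow(code, rpn, ideal, score, ranks[code])
        for code, rpn, ideal, score in rows
    ]


@dataclass(frozen=True)
class RankComparison:
    """Concordance report between two rankings of the same error set."""

    table: pd.DataFrame  # columns rank_a, rank_b, shift
    spearman: float
    kendall: float
    movers: tuple[str, ...]  # errors whose rank moved by >= threshold
    threshold: int


def compare_rankings(
    r1: Mapping[str, int],
    r2: Mapping[str, int],
    threshold: int = 5,
) -> RankComparison:
    """Compare two rankings (mappings error_code -> rank) of one error set.

    Reports Spearman and Kendall rank correlations and the errors whose
    rank moved by at least ``threshold`` places.
    """
    if set(r1) != set(r2):
        raise KeyError(
            f"rankings cover different errors: "
            f"{sorted(set(r1) ^ set(r2))} not shared"
        )
    codes = sorted(r1)
    a = [r1[c] for c in codes]
    b = [r2[c] for c in codes]
    table = pd.DataFrame(
        {"rank_a": a, "rank_b": b, "shift": [y - x for x, y in zip(a, b)]},
        index=pd.Index(codes, name="error_code"),
    )
    if len(codes) > 1:
        spearman = float(stats.spearmanr(a, b).statistic)
        kendall = float(stats.kendalltau(a, b).statistic)
    else:
        spearman = kendall = 1.0
    movers = tuple(
        c for c in codes if abs(r1[c] - r2[c]) >= threshold
    )
    return RankComparison(
        table=table,
        spearman=spearman,
        kendall=kendall,
        movers=movers,
        threshold=threshold,
    )
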