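"""Pooling many raters' linguistic evaluations with the IIFWA operator.

Each rater assigns one linguistic code per (error, attribute) cell.  Codes
are mapped through the matching scale and pooled with the interval-valued
intuitionistic fuzzy weighted averaging (IIFWA) operator

    IIFWA(x_1..x_n; w) = (1 - prod(1-a_j)^w_j,  1 - prod(1-b_j)^w_j;
                          prod c_j^w_j,         prod d_j^w_j)

with nonnegative weights summing to one.  IIFWA is idempotent (identical
inputs are returned unchanged), permutation-invariant, and bounded: every
component of the result lies between the smallest and largest corresponding
input component.

Rater weights default to equal (1/n).  When a rater skipped a cell, the
remaining raters' weights are renormalized within that cell so the weight
constraint still holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import IVIFNumber
from .scales import LinguisticScale

__all__ = [
    "AggregationError",
    "RatingPanel",
    "RatingRecord",
    "aggregate_panel",
    "iifwa",
    "read_aggregated_csv",
    "read_rater_weights_csv",
    "read_ratings_csv",
    "write_aggregated_csv",
]

WEIGHT_TOL = 1e-9

ATTRIBUTES = ("severity", "preventability", "occurrence")


class AggregationError(ValueError):
    """A panel cannot be aggregated (empty cell, bad weights, unknown attribute)."""


@dataclass(frozen=True)
class RatingRecord:
    """One rater's linguistic code for one error on one attribute."""

    rater_id: str
    error_code: str
    attribute: str
    code: str

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise AggregationError(
                f"unknown attribute {self.attribute!r} for error "
                f"{self.error_code!r} (expected one of {ATTRIBUTES})"
            )


@dataclass(frozen=True)
class RatingPanel:
    """A rater x error x attribute matrix of linguistic codes.

    ``rater_weights`` maps rater_id to its weight; weights must be
    nonnegative and sum to 1 (within 1e-9).
    """

    records: tuple[RatingRecord, ...]
    rater_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "rater_weights", dict(self.rater_weights))
        if not self.records:
            raise AggregationError("rating panel contains no records")
        for rid, w in self.rater_weights.items():
            if w < 0:
                raise AggregationError(f"rater {rid!r} has negative weight {w}")
        total = math.fsum(self.rater_weights.values())
        if abs(total - 1.0) > WEIGHT_TOL:
            raise AggregationError(
                f"rater weights must sum to 1, got {total!r}"
            )
        unknown = {r.rater_id for r in self.records} - set(self.rater_weights)
        if unknown:
            raise AggregationError(
                f"records from raters without a weight: {sorted(unknown)}"
            )

    @classmethod
    def with_equal_weights(
        cls, records: Iterable[RatingRecord]
    ) -> "RatingPanel":
        records = tuple(records)
        raters = sorted({r.rater_id for r in records})
        n = len(raters)
        return cls(records, {rid: 1.0 / n for rid in raters})

    @property
    def errors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.error_code)
        return tuple(seen)

    @property
    def attributes(self) -> tuple[str, ...]:
        present = {r.attribute for r in self.records}
        return tuple(a for a in ATTRIBUTES if a in present)

    def cells(self) -> dict[tuple[str, str], list[RatingRecord]]:
        out: dict[tuple[str, str], list[RatingRecord]] = {}
        for r in self.records:
            out.setdefault((r.error_code, r.attribute), []).append(r)
        return out


def iifwa(
    values: Sequence[IVIFNumber], weights: Sequence[float]
) -> IVIFNumber:
    """Weighted IIFWA average of IVIF numbers.

    Weights must be nonnegative, match ``values`` in length, and sum to 1.
    A zero weight contributes a factor of 1 even against a degenerate
    component (the 0**0 corner), so zero-weight entries never change the
    result.
    """
    if len(values) != len(weights):
        raise AggregationError(
            f"{len(values)} values but {len(weights)} weights"
        )
    if not values:
        raise AggregationError("iifwa of an empty sequence")
    if any(w < 0 for w in weights):
        raise AggregationError(f"negative weight in {list(weights)}")
    if abs(math.fsum(weights) - 1.0) > WEIGHT_TOL:
        raise AggregationError(
            f"weights must sum to 1, got {math.fsum(weights)!r}"
        )
    pa = pb = pc = pd_ = 1.0
    for v, w in zip(values, weights):
        if w == 0.0:
            continue
        a, b, c, d = v.as_tuple()
        pa *= (1.0 - a) ** w
        pb *= (1.0 - b) ** w
        pc *= c**w
        pd_ *= d**w
    return IVIFNumber(1.0 - pa, 1.0 - pb, pc, pd_)


def aggregate_panel(
    panel: RatingPanel, scales: Mapping[str, LinguisticScale]
) -> dict[tuple[str, str], IVIFNumber]:
    """IIFWA-aggregate a panel into one IVIF number per (error, attribute).

    Raters missing from a cell are dropped and the remaining weights are
    renormalized within the cell.  Every (error, attribute) combination
    spanned by the panel must have at least one rating.
    """
    cells = panel.cells()
    for error in panel.errors:
        for attribute in panel.attributes:
            if (error, attribute) not in cells:
                raise AggregationError(
                    f"no ratings for cell ({error!r}, {attribute!r})"
                )
    out: dict[tuple[str, str], IVIFNumber] = {}
    for (error, attribute), records in cells.items():
        scale = scales[attribute]
        values = [scale.lookup(r.code) for r in records]
        weights = [panel.rater_weights[r.rater_id] for r in records]
        total = math.fsum(weights)
        if total <= 0:
            raise AggregationError(
                f"cell ({error!r}, {attribute!r}) has zero total rater weight"
            )
        out[(error, attribute)] = iifwa(values, [w / total for w in weights])
    return out


# ---------------------------------------------------------------------------
# file formats


def read_ratings_csv(path: str | Path) -> tuple[RatingRecord, ...]:
    """Read a long-format ratings CSV.

    Required columns: rater_id, error_code, attribute, code.  Extra columns
    (e.g. error_name) are ignored.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"rater_id", "error_code", "attribute", "code"}
    missing = required - set(df.columns)
    if missing:
        raise AggregationError(
            f"ratings file {path} lacks columns: {sorted(missing)}"
        )
    if df.empty:
        raise AggregationError(f"ratings file {path} contains no records")
    return tuple(
        RatingRecord(
            rater_id=row.rater_id,
            error_code=row.error_code,
            attribute=row.attribute,
            code=row.code,
        )
        for row in df.itertuples()
    )


def read_rater_weights_csv(path: str | Path) -> dict[str, float]:
    """Read a rater-weights CSV with columns rater_id, weight."""
    df = pd.read_csv(path, dtype={"rater_id": str, "weight": float})
    return dict(zip(df["rater_id"], df["weight"]))


def write_aggregated_csv(
    aggregated: Mapping[tuple[str, str], IVIFNumber], path: str | Path
) -> None:
    """Write an aggregated matrix CSV (error_code, attribute, 4 components)."""
    rows = [
        {
            "error_code": error,
            "attribute": attribute,
            "mu_lo": v.mu_lo,
            "mu_hi": v.mu_hi,
            "nu_lo": v.nu_lo,
            "nu_hi": v.nu_hi,
        }
        for (error, attribute), v in aggregated.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aggregated_csv(
    path: str | Path,
) -> dict[tuple[str, str], IVIFNumber]:
    """Read an aggregated matrix CSV written by :func:`write_aggregated_csv`."""
    df = pd.read_csv(path)
    return {
        (str(row.error_code), str(row.attribute)): IVIFNumber(
            row.mu_lo, row.mu_hi, row.nu_lo, row.nu_hi
        )
        for row in df.itertuples()
    }
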