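"""Linguistic rating scales and their IVIF images.

Raters answer with short categorical codes ("EI", "4", "High", ...).  A
:class:`LinguisticScale` maps each code to the IVIF number that the analysis
actually computes with.  Three scales are bundled:

``severity`` and ``preventability``
    share one six-row table ranging from "extremely important" (EI / 1) down
    to "little important" (LI / 6).  All of its IVIF components are strictly
    positive, because the importance-score path raises these values to
    fractional powers and zeros would annihilate every downstream score.

``occurrence``
    a nine-term order-of-magnitude ladder from "Rare" (< 1 in 1e8) to
    "Extremely High" (1 in 10), each term carrying a probability band so that
    raw event probabilities or count/exposure pairs can be classified
    directly.  Here zero components are deliberate: the similarity-based
    index path tolerates them, and "Rare" with mu_lo = 0 is what makes the
    ideal case's membership lower bound collapse to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .core import IVIFNumber, IVIFValidationError

__all__ = [
    "LinguisticScale",
    "ScaleTerm",
    "ScaleError",
    "UnknownCodeError",
    "builtin_scales",
    "load_scales",
    "lookup",
    "occurrence_from_counts",
    "occurrence_from_probability",
]

ZERO_FREE_SCALES = frozenset({"severity", "preventability"})


class ScaleError(ValueError):
    """A scale definition violates an invariant."""


class UnknownCodeError(KeyError):
    """A linguistic code does not resolve in the scale."""


@dataclass(frozen=True)
class ScaleTerm:
    """One row of a linguistic scale."""

    code: str
    description: str
    ivif: IVIFNumber
    band: tuple[float, float] | None = None  # probability band (occurrence)
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered list of :class:`ScaleTerm` with code lookup.

    Codes and aliases resolve case-insensitively.  A scale named
    ``severity`` or ``preventability`` must be zero-free; a scale whose
    terms carry probability bands must have contiguous, non-overlapping,
    ordered bands.
    """

    name: str
    terms: tuple[ScaleTerm, ...]
    _index: dict[str, ScaleTerm] = field(
        default=None, repr=False, compare=False  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        index: dict[str, ScaleTerm] = {}
        for term in self.terms:
            for key in (term.code, *term.aliases):
                k = key.casefold()
                if k in index:
                    raise ScaleError(
                        f"duplicate code {key!r} in scale {self.name!r}"
                    )
                index[k] = term
        object.__setattr__(self, "_index", index)
        if self.name in ZERO_FREE_SCALES:
            for term in self.terms:
                if min(term.ivif.as_tuple()) <= 0.0:
                    raise ScaleError(
                        f"scale {self.name!r} must be zero-free but term "
                        f"{term.code!r} is {term.ivif}"
                    )
        bands = [t.band for t in self.terms if t.band is not None]
        if bands:
            if len(bands) != len(self.terms):
                raise ScaleError(
                    f"scale {self.name!r}: either all terms carry a "
                    "probability band or none do"
                )
            for lo, hi in bands:
                if not (0.0 <= lo < hi <= 1.0):
                    raise ScaleError(f"malformed band ({lo}, {hi})")
            for (_, hi), (lo2, _) in zip(bands, bands[1:]):
                if hi != lo2:
                    raise ScaleError(
                        f"bands must be contiguous and ordered; gap or "
                        f"overlap between {hi} and {lo2}"
                    )

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(t.code for t in self.terms)

    def term(self, code: str) -> ScaleTerm:
        try:
            return self._index[str(code).casefold()]
        except KeyError:
            raise UnknownCodeError(
                f"unknown code {code!r} for scale {self.name!r}; "
                f"valid codes: {', '.join(self.codes)}"
            ) from None

    def lookup(self, code: str) -> IVIFNumber:
        return self.term(code).ivif

    def term_from_probability(self, p: float) -> ScaleTerm:
        """Classify a probability into this scale's bands.

        Bands are half-open ``[lo, hi)`` with the top band closed, so an
        exact band edge joins the higher-frequency term.  Values below the
        first band's lower edge fall into the first term.
        """
        if self.terms[0].band is None:
            raise ScaleError(f"scale {self.name!r} carries no probability bands")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {p}")
        for term in reversed(self.terms):
            lo, _ = term.band  # type: ignore[misc]
            if p >= lo and term is not self.terms[0]:
                return term
        return self.terms[0]


# ---------------------------------------------------------------------------
# construction from config


def _scale_from_dict(payload: Mapping) -> LinguisticScale:
    terms = []
    for raw in payload["terms"]:
        band = raw.get("band")
        try:
            ivif = IVIFNumber.from_sequence(raw["ivif"])
        except IVIFValidationError as exc:
            raise ScaleError(
                f"term {raw.get('code')!r}: invalid IVIF quadruple ({exc})"
            ) from exc
        terms.append(
            ScaleTerm(
                code=str(raw["code"]),
                description=str(raw.get("description", "")),
                ivif=ivif,
                band=tuple(float(x) for x in band) if band else None,
                aliases=tuple(str(a) for a in raw.get("aliases", ())),
            )
        )
    return LinguisticScale(name=str(payload["name"]), terms=tuple(terms))


def load_scales(path: str | Path) -> dict[str, LinguisticScale]:
    """Load scale definitions from a YAML or JSON config file.

    The file maps scale names to ``{name, terms: [{code, description,
    ivif: [4 floats], band: [lo, hi], aliases: [...]}]}``.  The same
    invariants as for the bundled scales are enforced.
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return {name: _scale_from_dict(cfg) for name, cfg in payload.items()}


_BUILTIN: dict[str, LinguisticScale] | None = None


def builtin_scales() -> dict[str, LinguisticScale]:
    """The three bundled scales: severity, preventability, occurrence."""
    global _BUILTIN
    if _BUILTIN is None:
        with resources.files("ivifmea.data").joinpath("scales.yaml").open() as fh:
            payload = yaml.safe_load(fh)
        _BUILTIN = {n: _scale_from_dict(cfg) for n, cfg in payload.items()}
    return dict(_BUILTIN)


def lookup(scale: LinguisticScale, code: str) -> IVIFNumber:
    """The IVIF image of ``code`` in ``scale`` (case-insensitive, aliases ok)."""
    return scale.lookup(code)


def occurrence_from_probability(p: float) -> ScaleTerm:
    """Classify an event probability on the bundled occurrence ladder."""
    return builtin_scales()["occurrence"].term_from_probability(p)


def occurrence_from_counts(events: int, exposure: int) -> ScaleTerm:
    """Classify ``events / exposure`` on the bundled occurrence ladder.

    The caller chooses the exposure denominator (patients seen, tests
    performed, ...); the package never guesses one.
    """
    if events < 0:
        raise ValueError(f"event count must be nonnegative, got {events}")
    if not exposure > 0:
        raise ValueError(f"exposure must be positive, got {exposure}")
    return occurrence_from_probability(events / exposure)
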