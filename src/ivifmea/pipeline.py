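"""End-to-end orchestration, synthetic panels, and the bundled case study.

The bundled case study covers the 18 most-reported medical errors of the
Turkish national safety reporting system (laboratory, medication,
general/surgical and patient-related categories), with severity and
preventability already aggregated over a 122-member expert panel and
survey-derived attribute weights (0.387, 0.334, 0.279).  The per-error
occurrence levels shipped alongside are NOT survey data: they were
reverse-derived from the reference index table by inverting the weighted
RPN, and are flagged as such in their filename.

`run_analysis` drives the full chain: read ratings -> aggregate ->
score -> rank -> write reports.  `synthesize_panel` fabricates reproducible
rating panels (categorical draws per rater, error and attribute) for
stress-testing the aggregation and recovery behaviour of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (
    AggregationError,
    RatingPanel,
    RatingRecord,
    aggregate_panel,
    read_aggregated_csv,
    read_rater_weights_csv,
    read_ratings_csv,
)
from .core import IVIFNumber
from .scales import LinguisticScale, builtin_scales, load_scales
from .scoring import (
    DEFAULT_K1_GRID,
    AttributeWeights,
    ImportanceReport,
    RiskProfile,
    importance_table,
)
from .similarity import IndexRow, index_table

__all__ = [
    "AnalysisConfig",
    "RankingReport",
    "load_case_study",
    "load_reference_importance_table",
    "load_reference_index_table",
    "load_reference_rank_comparison",
    "run_analysis",
    "synthesize_panel",
]


def _data_path(name: str):
    return resources.files("ivifmea.data").joinpath(name)


# ---------------------------------------------------------------------------
# bundled case study


def load_case_study() -> tuple[list[RiskProfile], AttributeWeights]:
    """The bundled 18-error case study.

    Returns one :class:`RiskProfile` per error (severity and preventability
    from the aggregated expert panel, occurrence from the derived
    assignment) plus the survey-derived attribute weights.
    """
    with _data_path("aggregated_scores.csv").open() as fh:
        agg = pd.read_csv(fh)
    with _data_path("occurrence_levels_derived.csv").open() as fh:
        occ = pd.read_csv(fh, index_col="error_code")["term"]
    occurrence_scale = builtin_scales()["occurrence"]
    profiles = []
    for code, group in agg.groupby("error_code", sort=False):
        by_attr = {
            row.attribute: IVIFNumber(row.mu_lo, row.mu_hi, row.nu_lo, row.nu_hi)
            for row in group.itertuples()
        }
        first = group.iloc[0]
        profiles.append(
            RiskProfile(
                error_code=str(code),
                severity=by_attr["severity"],
                preventability=by_attr["preventability"],
                occurrence=occurrence_scale.lookup(occ[code]),
                error_name=str(first.error_name),
                category=str(first.category),
            )
        )
    with _data_path("attribute_weights.json").open() as fh:
        w = json.load(fh)
    return profiles, AttributeWeights(**w)


def load_reference_index_table() -> pd.DataFrame:
    """Published index report for the case study (RPN and ideal quadruples
    at 3 decimals, index scores and ranks), for cross-checking."""
    with _data_path("reference_index_table.csv").open() as fh:
        return pd.read_csv(fh, index_col="error_code")


def load_reference_importance_table() -> pd.DataFrame:
    """Published importance report (GIS score and rank per k1) for the case
    study, for cross-checking."""
    with _data_path("reference_importance_table.csv").open() as fh:
        return pd.read_csv(fh, index_col="error_code")


def load_reference_rank_comparison() -> pd.DataFrame:
    """Published index-rank vs reported-count-rank comparison."""
    with _data_path("reference_rank_comparison.csv").open() as fh:
        return pd.read_csv(fh, index_col="error_code")


# ---------------------------------------------------------------------------
# synthetic panels


def synthesize_panel(
    n_raters: int,
    errors: Sequence[str],
    attribute_distributions: Mapping[str, Mapping[str, float]],
    rater_weight_mode: Literal["equal", "dirichlet"] = "equal",
    seed: int | None = None,
) -> RatingPanel:
    """Fabricate a reproducible rating panel.

    Each rater independently draws one linguistic code per error and
    attribute from the given categorical distribution
    (``attribute -> {code: probability}``); marginal code frequencies
    therefore converge to the supplied distributions as the panel grows.
    ``rater_weight_mode='equal'`` gives every rater weight 1/n (the default
    assumption for expert panels); ``'dirichlet'`` draws uneven weights for
    stress tests.  A fixed seed reproduces the panel exactly.
    """
    if n_raters < 1:
        raise ValueError(f"need at least one rater, got {n_raters}")
    rng = np.random.default_rng(seed)
    dists = {}
    for attribute, dist in attribute_distributions.items():
        codes = list(dist)
        probs = np.asarray([dist[c] for c in codes], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"distribution for {attribute!r} must be nonnegative and "
                f"sum to 1, got {dict(dist)}"
            )
        dists[attribute] = (codes, probs)
    rater_ids = [f"r{i + 1:04d}" for i in range(n_raters)]
    records = []
    for rid in rater_ids:
        for error in errors:
            for attribute, (codes, probs) in dists.items():
                code = codes[int(rng.choice(len(codes), p=probs))]
                records.append(
                    RatingRecord(
                        rater_id=rid,
                        error_code=str(error),
                        attribute=attribute,
                        code=code,
                    )
                )
    if rater_weight_mode == "equal":
        weights = {rid: 1.0 / n_raters for rid in rater_ids}
    elif rater_weight_mode == "dirichlet":
        draw = rng.dirichlet(np.ones(n_raters))
        weights = dict(zip(rater_ids, draw.tolist()))
    else:
        raise ValueError(f"unknown rater_weight_mode {rater_weight_mode!r}")
    return RatingPanel(tuple(records), weights)


# ---------------------------------------------------------------------------
# end-to-end analysis


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one analysis run.

    Exactly one of ``ratings_path`` (raw per-rater codes, long CSV) or
    ``aggregated_path`` (pre-aggregated matrix CSV) must be given.
    Occurrence can come from the ratings themselves (linguistic codes), a
    per-error CSV of linguistic terms, probabilities, or counts+exposure.
    """

    output_dir: str | Path
    ratings_path: str | Path | None = None
    aggregated_path: str | Path | None = None
    rater_weights_path: str | Path | None = None
    scales_path: str | Path | None = None
    attribute_weights: AttributeWeights = field(default_factory=AttributeWeights)
    occurrence_path: str | Path | None = None
    occurrence_source: Literal["linguistic", "probability", "counts"] = "linguistic"
    k1_grid: tuple[float, ...] = DEFAULT_K1_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.ratings_path is None) == (self.aggregated_path is None):
            raise ValueError(
                "exactly one of ratings_path or aggregated_path is required"
            )


@dataclass(frozen=True)
class RankingReport:
    """Output of :func:`run_analysis`.

    Errors with occurrence data appear in the index path; errors without
    appear only in the importance path (which always covers every error,
    since it needs no occurrence information).
    """

    index_rows: tuple[IndexRow, ...]
    importance: ImportanceReport
    profiles: tuple[RiskProfile, ...]
    metadata: dict


def _occurrence_map(
    config: AnalysisConfig, scale: LinguisticScale
) -> dict[str, IVIFNumber]:
    if config.occurrence_path is None:
        return {}
    df = pd.read_csv(config.occurrence_path)
    out: dict[str, IVIFNumber] = {}
    for row in df.itertuples():
        code = str(row.error_code)
        if config.occurrence_source == "linguistic":
            out[code] = scale.lookup(str(row.term))
        elif config.occurrence_source == "probability":
            out[code] = scale.term_from_probability(float(row.probability)).ivif
        elif config.occurrence_source == "counts":
            events, exposure = int(row.events), int(row.exposure)
            if exposure <= 0:
                raise ValueError(f"exposure must be positive for {code!r}")
            out[code] = scale.term_from_probability(events / exposure).ivif
        else:
            raise ValueError(
                f"unknown occurrence_source {config.occurrence_source!r}"
            )
    return out


def run_analysis(config: AnalysisConfig) -> RankingReport:
    """Run the full prioritization chain and write report files.

    Writes ``index_report.csv``, ``importance_report.csv`` and
    ``report.json`` (full precision plus metadata) into
    ``config.output_dir``.  Deterministic: identical config and inputs give
    byte-identical outputs.
    """
    scales = (
        load_scales(config.scales_path)
        if config.scales_path
        else builtin_scales()
    )
    if config.ratings_path is not None:
        records = read_ratings_csv(config.ratings_path)
        if config.rater_weights_path is not None:
            weights = read_rater_weights_csv(config.rater_weights_path)
            panel = RatingPanel(records, weights)
        else:
            panel = RatingPanel.with_equal_weights(records)
        aggregated = aggregate_panel(panel, scales)
    else:
        aggregated = read_aggregated_csv(config.aggregated_path)

    occurrence = _occurrence_map(config, scales["occurrence"])
    errors: dict[str, dict[str, IVIFNumber]] = {}
    for (code, attribute), value in aggregated.items():
        errors.setdefault(code, {})[attribute] = value
    profiles = []
    for code, attrs in errors.items():
        missing = {"severity", "preventability"} - set(attrs)
        if missing:
            raise AggregationError(
                f"error {code!r} lacks aggregated {sorted(missing)}"
            )
        profiles.append(
            RiskProfile(
                error_code=code,
                severity=attrs["severity"],
                preventability=attrs["preventability"],
                occurrence=occurrence.get(code, attrs.get("occurrence")),
            )
        )
    profiles.sort(key=lambda p: p.error_code)

    with_occ = [p for p in profiles if p.occurrence is not None]
    index_rows = tuple(index_table(with_occ, config.attribute_weights))
    importance = importance_table(
        profiles, config.attribute_weights, config.k1_grid
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_df = pd.DataFrame(
        {
            "error_code": [r.error_code for r in index_rows],
            "rpn": [str(r.rpn.round(3)) for r in index_rows],
            "ideal": [str(r.ideal.round(3)) for r in index_rows],
            "index_score": [round(r.index_score, 3) for r in index_rows],
            "rank": [r.rank for r in index_rows],
        }
    )
    index_df.to_csv(out_dir / "index_report.csv", index=False)
    imp_df = importance.table.round(3)
    imp_df.to_csv(out_dir / "importance_report.csv")

    digest = hashlib.sha256()
    for path in (config.ratings_path, config.aggregated_path, config.occurrence_path):
        if path is not None:
            digest.update(Path(path).read_bytes())
    digest.update(
        repr(
            (
                config.occurrence_source,
                config.attribute_weights,
                config.k1_grid,
                config.seed,
            )
        ).encode()
    )
    config_digest = digest.hexdigest()[:16]
    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_digest,
        "n_errors": len(profiles),
        "n_index_path": len(index_rows),
        "ranking_stable_across_k1": importance.stable,
    }
    payload = {
        "metadata": metadata,
        "index": [
            {
                "error_code": r.error_code,
                "rpn": r.rpn.as_list(),
                "ideal": r.ideal.as_list(),
                "index_score": r.index_score,
                "rank": r.rank,
            }
            for r in index_rows
        ],
        "importance": json.loads(importance.table.to_json(orient="index")),
    }
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return RankingReport(
        index_rows=index_rows,
        importance=importance,
        profiles=tuple(profiles),
        metadata=metadata,
    )
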