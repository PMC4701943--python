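"""Content-based retrieval over per-spine feature tables.

Every query starts from min–max normalized features (so heterogeneous units
— µm³, µm², µm, mV — become comparable and all scores land in [0, 1]) and a
weight per selected feature in [−1, 1]: positive weights seek similarity /
large values, negative weights the opposite.

Two query modes:

*Cell distribution* — ranks every spine by the weighted sum of its own
normalized feature values; the emitted score is the rank percentile
(position / (N−1), ascending), so with a single positive-weight feature the
largest value scores exactly 1.  Raw weighted sums are kept alongside for
transparency.

*Spine comparison* — compares every spine against the *signature* of a
query set (the per-feature mean of the query spines' normalized values).
Per feature, similarity is 1 − |f̂ − c|; a positive weight rewards
similarity, a negative weight rewards dissimilarity (1 minus it); the score
is the |w|-weighted average of the contributions, hence always in [0, 1],
and a singleton query retrieves itself with score 1.

Spines missing any selected feature are unscored (no imputation) and listed
separately.  Ties in the ranking break deterministically by spine id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import QueryError
from .io_formats import FeatureTable

__all__ = [
    "QuerySpec",
    "ScoreResult",
    "RangeFilter",
    "normalize",
    "signature",
    "cell_distribution_query",
    "spine_comparison_query",
    "histogram",
    "range_filter",
    "rescale_range",
]


@dataclass(frozen=True)
class QuerySpec:
    """A retrieval request: mode, per-feature weights, optional query set."""

    mode: str
    weights: dict[str, float]
    query_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("cell_distribution", "spine_comparison"):
            raise QueryError(f"unknown query mode {self.mode!r}")
        selected = {k: w for k, w in self.weights.items() if w != 0.0}
        if not selected:
            raise QueryError("at least one feature with a nonzero weight is required")
        bad = {k: w for k, w in selected.items() if not -1.0 <= w <= 1.0}
        if bad:
            raise QueryError(f"weights must lie in [-1, 1]: {bad}")
        if self.mode == "spine_comparison" and not self.query_ids:
            raise QueryError("spine_comparison requires at least one query id")
        object.__setattr__(self, "query_ids", tuple(self.query_ids))

    @property
    def selected_features(self) -> list[str]:
        return [k for k, w in self.weights.items() if w != 0.0]


@dataclass
class ScoreResult:
    """Scores in [0, 1] per scored spine, plus the descending-score ranking.

    ``raw_scores`` carries the pre-percentile weighted sums for cell
    distribution queries; ``unscored`` lists spines excluded for missing
    features.
    """

    scores: dict[str, float]
    ranking: list[str]
    query: QuerySpec
    raw_scores: dict[str, float] | None = None
    unscored: list[str] = field(default_factory=list)

    def __post_init__(self):
        vals = np.array(list(self.scores.values()), dtype=float)
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12):
            raise QueryError("scores escaped [0, 1]")
        if sorted(self.ranking) != sorted(self.scores):
            raise QueryError("ranking must permute exactly the scored ids")


@dataclass(frozen=True)
class RangeFilter:
    """Score window [lo, hi]; ``complement`` selects the spines outside it."""

    lo: float = 0.0
    hi: float = 1.0
    complement: bool = False

    def __post_init__(self):
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError(f"need 0 <= lo <= hi <= 1, got [{self.lo}, {self.hi}]")


# ---------------------------------------------------------------------------
# Normalization and signatures
# ---------------------------------------------------------------------------

def _normalized_matrix(
    table: FeatureTable, features: list[str]
) -> tuple[np.ndarray, list[str]]:
    """(n_records, n_features) of min–max normalized values; NaN = missing."""
    cols = []
    for name in features:
        raw = table.feature_array(name)
        present = ~np.isnan(raw)
        if not present.any():
            raise QueryError(f"feature {name!r} has no values in the table")
        lo = raw[present].min()
        hi = raw[present].max()
        if hi > lo:
            col = (raw - lo) / (hi - lo)
        else:  # constant feature: everything maps to 0 by convention
            col = np.where(present, 0.0, np.nan)
        cols.append(col)
    return np.column_stack(cols), table.ids


def normalize(table: FeatureTable, features: list[str]) -> FeatureTable:
    """Min–max normalize the named features; missing values stay missing."""
    X, ids = _normalized_matrix(table, features)
    records = []
    for row, rec in zip(X, table.records):
        feats = dict(rec.features)
        for j, name in enumerate(features):
            if not np.isnan(row[j]):
                feats[name] = float(row[j])
            else:
                feats.pop(name, None)
        records.append(replace(rec, features=feats))
    return FeatureTable(records, list(table.feature_names), dict(table.spine_classes))


def signature(table: FeatureTable, query_ids, features: list[str]) -> np.ndarray:
    """Per-feature mean of normalized values over the query set."""
    ids = table.ids
    missing = [q for q in query_ids if q not in set(ids)]
    if missing:
        raise QueryError(f"query ids not in table: {missing}")
    if not query_ids:
        raise QueryError("empty query set")
    X, _ = _normalized_matrix(table, features)
    pos = {i: k for k, i in enumerate(ids)}
    rows = X[[pos[q] for q in query_ids]]
    with np.errstate(invalid="ignore"):
        sig = np.nanmean(rows, axis=0)
    if np.isnan(sig).any():
        bad = [features[j] for j in np.flatnonzero(np.isnan(sig))]
        raise QueryError(f"query set has no values for feature(s) {bad}")
    return sig


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _ranking(scores: dict[str, float]) -> list[str]:
    return sorted(scores, key=lambda i: (-scores[i], i))


def cell_distribution_query(table: FeatureTable, spec: QuerySpec) -> ScoreResult:
    """Rank all spines by their own weighted normalized feature values.

    Final scores are rank percentiles: sorting the raw weighted sums
    ascending (ties by id), a spine at position p among N scored spines
    scores p/(N−1); a single scored spine scores 1.
    """
    if spec.mode != "cell_distribution":
        raise QueryError(f"expected cell_distribution spec, got {spec.mode!r}")
    feats = spec.selected_features
    w = np.array([spec.weights[f] for f in feats])
    X, ids = _normalized_matrix(table, feats)
    scored = ~np.isnan(X).any(axis=1)
    if not scored.any():
        raise QueryError("no spine carries all selected features")

    raw = X[scored] @ w
    sids = [i for i, s in zip(ids, scored) if s]
    order = sorted(range(len(sids)), key=lambda k: (raw[k], sids[k]))
    N = len(sids)
    scores: dict[str, float] = {}
    raws: dict[str, float] = {}
    for pos, k in enumerate(order):
        scores[sids[k]] = pos / (N - 1) if N > 1 else 1.0
        raws[sids[k]] = float(raw[k])
    return ScoreResult(
        scores=scores,
        ranking=_ranking(scores),
        query=spec,
        raw_scores=raws,
        unscored=[i for i, s in zip(ids, scored) if not s],
    )


def spine_comparison_query(table: FeatureTable, spec: QuerySpec) -> ScoreResult:
    """Rank all spines by weighted similarity to the query-set signature."""
    if spec.mode != "spine_comparison":
        raise QueryError(f"expected spine_comparison spec, got {spec.mode!r}")
    feats = spec.selected_features
    w = np.array([spec.weights[f] for f in feats])
    sig = signature(table, list(spec.query_ids), feats)
    X, ids = _normalized_matrix(table, feats)
    scored = ~np.isnan(X).any(axis=1)
    if not scored.any():
        raise QueryError("no spine carries all selected features")

    sim = 1.0 - np.abs(X[scored] - sig)          # per-feature similarity
    contrib = np.where(w > 0, sim, 1.0 - sim)    # negative weight = dissimilarity
    score_vals = (contrib * np.abs(w)).sum(axis=1) / np.abs(w).sum()
    sids = [i for i, s in zip(ids, scored) if s]
    scores = {i: float(np.clip(v, 0.0, 1.0)) for i, v in zip(sids, score_vals)}
    return ScoreResult(
        scores=scores,
        ranking=_ranking(scores),
        query=spec,
        unscored=[i for i, s in zip(ids, scored) if not s],
    )


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def histogram(scores: dict[str, float] | ScoreResult, n_bins: int = 50) -> np.ndarray:
    """Counts over ``n_bins`` equal-width bins on [0, 1] (last bin closed)."""
    vals = _values(scores)
    if vals.size == 0:
        raise QueryError("no scores to histogram")
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return counts


def range_filter(
    scores: dict[str, float] | ScoreResult, flt: RangeFilter
) -> list[str]:
    """Ids whose score lies in [lo, hi] (or exactly the others if complement)."""
    d = _mapping(scores)
    inside = [i for i, v in d.items() if flt.lo <= v <= flt.hi]
    if not flt.complement:
        return sorted(inside)
    return sorted(set(d) - set(inside))


def rescale_range(
    scores: dict[str, float] | ScoreResult, lo: float, hi: float
) -> dict[str, float]:
    """Linearly remap [lo, hi] → [0, 1] with clipping — the dynamic-range
    rescale used to spread visually indistinguishable score subsets."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    d = _mapping(scores)
    return {
        i: float(np.clip((v - lo) / (hi - lo), 0.0, 1.0)) for i, v in d.items()
    }


def _mapping(scores) -> dict[str, float]:
    return scores.scores if isinstance(scores, ScoreResult) else dict(scores)


def _values(scores) -> np.ndarray:
    return np.array(list(_mapping(scores).values()), dtype=float)
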