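"""Comparison stages: extreme-node sets, cross-measure rank agreement,
top-k concordance, and scoring against ground-truth influential nodes.

Eccentricity runs opposite to the other measures (small = central), so every
ranking step here works on its negation; the adjustment is recorded on the
result objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .centrality import MEASURES, CentralityProfile, CentralityVector
from .graph import round_sig
from .synth import AnnotatedGraph

TIE_TOL = 1e-9

#: measures whose raw value decreases with centrality; negated before ranking
INVERTED_MEASURES = ("eccentricity",)

__all__ = [
    "TIE_TOL",
    "INVERTED_MEASURES",
    "ExtremeSummary",
    "CorrelationMatrix",
    "TopKOverlap",
    "ValidationReport",
    "extreme_node_sets",
    "rank_correlation",
    "top_k_overlap",
    "score_against_ground_truth",
]


@dataclass(frozen=True)
class ExtremeSummary:
    measure: str
    max_value: float
    argmax_nodes: frozenset
    min_value: float
    argmin_nodes: frozenset
    constant: bool
    histogram_max_count: int
    histogram_min_count: int
    """End-bin counts of a 10-bin histogram over the score range; published
    caption counts sometimes reflect binning rather than exact ties."""


def extreme_node_sets(vec: CentralityVector, tol: float = TIE_TOL) -> ExtremeSummary:
    """Nodes within ``tol`` of the max/min score, after rounding to 12
    significant digits; also reports 10-bin histogram end-bin counts."""
    if not vec.scores:
        raise ValueError("empty centrality vector")
    rounded = {v: round_sig(float(s)) for v, s in vec.scores.items()}
    values = np.array(list(rounded.values()))
    mx, mn = float(values.max()), float(values.min())
    constant = (mx - mn) <= tol
    argmax = frozenset(v for v, s in rounded.items() if mx - s <= tol)
    argmin = frozenset(v for v, s in rounded.items() if s - mn <= tol)
    if constant:
        hist_max = hist_min = len(rounded)
    else:
        counts, _ = np.histogram(values, bins=np.linspace(mn, mx, 11))
        hist_min, hist_max = int(counts[0]), int(counts[-1])
    return ExtremeSummary(
        measure=vec.measure,
        max_value=mx,
        argmax_nodes=argmax,
        min_value=mn,
        argmin_nodes=argmin,
        constant=constant,
        histogram_max_count=hist_max,
        histogram_min_count=hist_min,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    method: str
    measures: tuple[str, ...]
    values: np.ndarray
    adjusted: tuple[str, ...]
    n_shared: int

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.measures.index(a), self.measures.index(b)])


def _shared_nodes(profile: CentralityProfile) -> list[str]:
    shared = None
    for m in MEASURES:
        keys = set(profile[m].scores)
        shared = keys if shared is None else shared & keys
    return sorted(shared)


def _adjusted_column(profile: CentralityProfile, measure: str, nodes: Sequence[str]) -> np.ndarray:
    sign = -1.0 if measure in INVERTED_MEASURES else 1.0
    return np.array([sign * profile[measure].scores[v] for v in nodes])


def rank_correlation(profile: CentralityProfile, method: str = "kendall") -> CorrelationMatrix:
    """Tie-aware rank correlation (Kendall tau-b or Spearman) between all
    measure pairs, on the nodes every vector covers.

    A constant vector has no defined rank correlation; such entries are NaN
    (the diagonal is pinned to 1).
    """
    if method not in ("kendall", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    nodes = _shared_nodes(profile)
    if len(nodes) < 3:
        raise ValueError(f"only {len(nodes)} shared nodes; need at least 3")
    cols = {m: _adjusted_column(profile, m, nodes) for m in MEASURES}
    k = len(MEASURES)
    mat = np.eye(k)
    corr = stats.kendalltau if method == "kendall" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            r = corr(cols[MEASURES[i]], cols[MEASURES[j]]).statistic
            mat[i, j] = mat[j, i] = r
    return CorrelationMatrix(
        method=method,
        measures=MEASURES,
        values=mat,
        adjusted=INVERTED_MEASURES,
        n_shared=len(nodes),
    )


def ranked_nodes(profile: CentralityProfile, measure: str) -> list[str]:
    """Nodes ordered most-central first; ties broken by lexicographic label."""
    scores = profile[measure].scores
    sign = -1.0 if measure in INVERTED_MEASURES else 1.0
    return sorted(scores, key=lambda v: (-sign * round_sig(float(scores[v])), v))


@dataclass(frozen=True)
class TopKOverlap:
    k: int
    measures: tuple[str, ...]
    values: np.ndarray
    boundary_ties: Mapping[str, bool]
    """Per measure: whether the score at rank k ties the score at rank k+1,
    i.e. whether the lexicographic tie-break actually decided membership."""

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.measures.index(a), self.measures.index(b)])


def top_k_overlap(profile: CentralityProfile, k: int) -> TopKOverlap:
    """|top-k(a) ∩ top-k(b)| / k for every measure pair."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tops: dict[str, set] = {}
    ties: dict[str, bool] = {}
    for m in MEASURES:
        order = ranked_nodes(profile, m)
        if k > len(order):
            raise ValueError(f"k={k} exceeds node count {len(order)} for {m}")
        tops[m] = set(order[:k])
        scores = profile[m].scores
        ties[m] = k < len(order) and abs(
            round_sig(float(scores[order[k - 1]])) - round_sig(float(scores[order[k]]))
        ) <= TIE_TOL
    n = len(MEASURES)
    mat = np.zeros((n, n))
    for i, a in enumerate(MEASURES):
        for j, b in enumerate(MEASURES):
            mat[i, j] = len(tops[a] & tops[b]) / k
    return TopKOverlap(k=k, measures=MEASURES, values=mat, boundary_ties=ties)


@dataclass(frozen=True)
class MeasureScore:
    hits: int
    reciprocal_rank: float
    best_node: str
    best_rank: int


@dataclass(frozen=True)
class ValidationReport:
    dataset: str
    k: int
    scores: Mapping[str, MeasureScore]
    warnings: tuple[str, ...] = ()


def score_against_ground_truth(
    profile: CentralityProfile, annotated: AnnotatedGraph, k: int = 5
) -> ValidationReport:
    """Per measure: ground-truth hits in the top k, and the reciprocal of the
    best ground-truth node's competition rank (1 + number of strictly better
    scores).  An empty ground-truth set yields a warning and no scores."""
    if k < 1:
        raise ValueError("k must be >= 1")
    truth = set(annotated.influential)
    if not truth:
        return ValidationReport(
            dataset=annotated.construction,
            k=k,
            scores={},
            warnings=("ground-truth influential set is empty; nothing to score",),
        )
    warnings: list[str] = []
    scores: dict[str, MeasureScore] = {}
    for m in MEASURES:
        vec = profile[m].scores
        present = truth & set(vec)
        if not present:
            warnings.append(f"{m}: no ground-truth node in the scored node set")
            continue
        order = ranked_nodes(profile, m)
        kk = min(k, len(order))
        hits = len(set(order[:kk]) & present)
        sign = -1.0 if m in INVERTED_MEASURES else 1.0
        adj = {v: sign * round_sig(float(s)) for v, s in vec.items()}
        best = min(present, key=lambda v: (-adj[v], v))
        rank = 1 + sum(1 for v in adj.values() if v > adj[best] + TIE_TOL)
        scores[m] = MeasureScore(
            hits=hits, reciprocal_rank=1.0 / rank, best_node=best, best_rank=rank
        )
    return ValidationReport(
        dataset=annotated.construction, k=k, scores=scores, warnings=tuple(warnings)
    )
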