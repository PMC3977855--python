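"""From-scratch implementations of five node-centrality measures.

degree       deg(v) / (n - 1)                    (raw counts via a flag)
betweenness  sum over unordered pairs {s,t} of sigma_st(v)/sigma_st,
             endpoints excluded, unnormalized    (Brandes accumulation)
closeness    1 / farness(v)                      (inverse total distance)
eccentricity max_t d(v, t)                       (raw hop count)
eigenvector  dominant adjacency eigenvector      (power iteration)

Closeness and eccentricity are undefined across components and are therefore
computed on the largest connected component only, with the restriction
recorded on the returned vector.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .graph import Graph, largest_connected_component

logger = logging.getLogger(__name__)

MEASURES = ("degree", "betweenness", "closeness", "eccentricity", "eigenvector")

__all__ = [
    "MEASURES",
    "CentralityVector",
    "CentralityProfile",
    "EigenResult",
    "ConvergenceError",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eccentricity_centrality",
    "eigenvector_centrality",
    "compute_profile",
]


@dataclass(frozen=True)
class CentralityVector:
    measure: str
    scores: Mapping[str, float]
    normalization: str
    restricted_to: frozenset | None = None
    """Node set of the component the measure was restricted to, if any."""

    def argmax(self) -> str:
        return min(self.scores, key=lambda v: (-self.scores[v], v))

    def argmin(self) -> str:
        return min(self.scores, key=lambda v: (self.scores[v], v))


@dataclass(frozen=True)
class EigenResult:
    eigenvalue: float
    vector: CentralityVector
    iterations: int
    residual: float
    shifted: bool = False
    """True when a +I diagonal shift was needed to break a bipartite
    oscillation; the dominant eigenvector is unchanged by the shift."""


@dataclass(frozen=True)
class CentralityProfile:
    graph_id: str
    vectors: Mapping[str, CentralityVector]
    eigen: EigenResult
    warnings: tuple[str, ...] = ()

    def __getitem__(self, measure: str) -> CentralityVector:
        return self.vectors[measure]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


def degree_centrality(g: Graph, normalized: bool = True) -> CentralityVector:
    """Fraction of possible neighbors, deg(v)/(n-1); raw counts if requested."""
    if g.n < 2:
        raise ValueError("degree centrality needs at least 2 nodes (n-1 normalization)")
    denom = (g.n - 1) if normalized else 1
    scores = {v: g.degree(v) / denom for v in g.nodes}
    return CentralityVector("degree", scores, "deg/(n-1)" if normalized else "raw")


def betweenness_centrality(g: Graph, normalized: bool = False) -> CentralityVector:
    """Shortest-path load of each node as an interior vertex.

    Brandes' dependency accumulation; unordered source/target pairs with
    endpoints excluded.  Optional normalization divides by C(n-1, 2).
    """
    nodes = g.nodes
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest-path DAG
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0)
        sigma[s] = 1
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # back-propagation of pair dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    scale = 2.0  # each unordered pair was visited from both endpoints
    if normalized:
        if g.n < 3:
            raise ValueError("normalized betweenness needs n >= 3")
        scale *= (g.n - 1) * (g.n - 2) / 2.0
    scores = {v: bc[v] / scale for v in nodes}
    norm = "pairs/C(n-1,2)" if normalized else "unordered pairs, unnormalized"
    return CentralityVector("betweenness", scores, norm)


def _component_distances(g: Graph):
    """(component graph, all-pairs hop distances) on the largest component."""
    comp = largest_connected_component(g)
    if comp.n < g.n:
        logger.warning(
            "graph is disconnected; restricting to largest component (%d of %d nodes)",
            comp.n,
            g.n,
        )
    if comp.n < 2:
        raise ValueError("largest component has a single node; measure undefined")
    dist: dict[str, dict[str, int]] = {}
    for s in comp.nodes:
        d = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in comp.neighbors(v):
                if w not in d:
                    d[w] = d[v] + 1
                    queue.append(w)
        dist[s] = d
    return comp, dist


def closeness_centrality(g: Graph, variant: str = "inverse_farness") -> CentralityVector:
    """Inverse farness 1/sum_t d(v,t), on the largest connected component.

    ``variant='freeman'`` rescales to (n_c - 1)/farness so scores are
    comparable across graph sizes.
    """
    if variant not in ("inverse_farness", "freeman"):
        raise ValueError(f"unknown closeness variant {variant!r}")
    comp, dist = _component_distances(g)
    numer = 1.0 if variant == "inverse_farness" else comp.n - 1
    scores = {v: numer / sum(dist[v].values()) for v in comp.nodes}
    restricted = frozenset(comp.nodes) if comp.n < g.n else None
    return CentralityVector("closeness", scores, variant, restricted)


def eccentricity_centrality(g: Graph) -> CentralityVector:
    """Largest hop distance from each node, on the largest component.

    Note: higher eccentricity means *less* central; comparison stages invert
    the sign, and report layers may export the reciprocal.
    """
    comp, dist = _component_distances(g)
    scores = {v: float(max(dist[v].values())) for v in comp.nodes}
    restricted = frozenset(comp.nodes) if comp.n < g.n else None
    return CentralityVector("eccentricity", scores, "raw max distance", restricted)


def _adjacency(g: Graph) -> tuple[np.ndarray, list[str]]:
    nodes = g.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((g.n, g.n))
    for u, v in g.edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    return a, nodes


def _power_iterate(a: np.ndarray, tol: float, max_iter: int):
    """Power iteration from the uniform positive start vector.

    Converged when both the successive-iterate max-norm difference and the
    eigen-residual max|A v - lambda v| drop below ``tol``.
    """
    n = a.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    residual = np.inf
    for it in range(1, max_iter + 1):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return v, it, np.inf, False
        w /= norm
        diff = np.max(np.abs(w - v))
        lam = w @ a @ w
        residual = np.max(np.abs(a @ w - lam * w))
        v = w
        if diff < tol and residual <= tol:
            return v, it, residual, True
    return v, max_iter, residual, False


def eigenvector_centrality(
    g: Graph, tol: float = 1e-10, max_iter: int = 1000
) -> EigenResult:
    """Dominant adjacency eigenvector via power iteration.

    On detection of the bipartite +/-lambda oscillation the iteration is
    re-run on A + I (same eigenvectors, spectrum shifted off symmetry) and
    the shift is recorded.  The reported eigenvalue is always the Rayleigh
    quotient with the *unshifted* adjacency matrix.
    """
    if g.m < 1:
        raise ValueError("eigenvector centrality needs at least one edge")
    a, nodes = _adjacency(g)
    vec, iters, residual, ok = _power_iterate(a, tol, max_iter)
    shifted = False
    if not ok:
        vec2, it2, res2, ok2 = _power_iterate(a + np.eye(g.n), tol, max_iter)
        if ok2:
            vec, shifted = vec2, True
            iters += it2
            lam2 = vec @ a @ vec
            residual = float(np.max(np.abs(a @ vec - lam2 * vec)))
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(residual {residual:.3e}); graph may be bipartite",
                residual=float(residual),
                iterations=iters + it2,
            )
    lam = float(vec @ a @ vec)
    vec = np.where(np.abs(vec) < 1e-300, 0.0, vec)  # flush denormals
    scores = {node: float(x) for node, x in zip(nodes, vec)}
    cv = CentralityVector("eigenvector", scores, "unit Euclidean norm")
    return EigenResult(
        eigenvalue=lam,
        vector=cv,
        iterations=iters,
        residual=float(residual),
        shifted=shifted,
    )


def compute_profile(
    g: Graph,
    graph_id: str = "graph",
    degree_normalized: bool = True,
    betweenness_normalized: bool = False,
    closeness_variant: str = "inverse_farness",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityProfile:
    """All five centrality vectors on one graph, defaults as documented above."""
    if g.n < 2:
        raise ValueError("profile needs at least 2 nodes")
    warnings: list[str] = []
    deg = degree_centrality(g, normalized=degree_normalized)
    btw = betweenness_centrality(g, normalized=betweenness_normalized)
    clo = closeness_centrality(g, variant=closeness_variant)
    ecc = eccentricity_centrality(g)
    eig = eigenvector_centrality(g, tol=tol, max_iter=max_iter)
    if clo.restricted_to is not None:
        warnings.append(
            "closeness/eccentricity restricted to the largest connected "
            f"component ({len(clo.restricted_to)} of {g.n} nodes)"
        )
    if eig.shifted:
        warnings.append("eigenvector computed with +I damping shift")
    vectors = {
        "degree": deg,
        "betweenness": btw,
        "closeness": clo,
        "eccentricity": ecc,
        "eigenvector": eig.vector,
    }
    return CentralityProfile(
        graph_id=graph_id, vectors=vectors, eigen=eig, warnings=tuple(warnings)
    )
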