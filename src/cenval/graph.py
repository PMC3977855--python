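"""Undirected simple graph model, text I/O and shortest-path primitives.

The graph type is deliberately minimal: labeled nodes, unordered edges,
hop-count distances.  Directed or weighted inputs are collapsed on read,
because every downstream score is defined on undirected, unweighted graphs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "NodeDistance",
    "GeodesicCounts",
    "GMLParseError",
    "read_gml",
    "read_edge_list",
    "bfs_distances",
    "count_geodesics",
    "largest_connected_component",
    "write_annotated_gml",
    "round_sig",
]


def round_sig(x: float, digits: int = 12) -> float:
    """Round ``x`` to ``digits`` significant digits (cross-platform diffable)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


class Graph:
    """An undirected simple graph over string node labels.

    Nodes keep insertion order; edges are set-valued (no duplicates, no
    self-loops).  Instances are treated as immutable after construction.
    """

    __slots__ = ("_adj",)

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        adj: dict[str, set[str]] = {}
        for v in nodes:
            adj.setdefault(str(v), set())
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            adj.setdefault(u, set())
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
        self._adj = adj

    @property
    def nodes(self) -> list[str]:
        return list(self._adj)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges as lexicographically sorted (u, v) pairs with u < v."""
        seen = set()
        for u, nbrs in self._adj.items():
            for v in nbrs:
                seen.add((u, v) if u < v else (v, u))
        return sorted(seen)

    @property
    def n(self) -> int:
        return len(self._adj)

    @property
    def m(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def neighbors(self, v: str) -> list[str]:
        return sorted(self._adj[v])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def subgraph(self, nodes: Iterable[str]) -> "Graph":
        keep = set(nodes)
        unknown = keep - set(self._adj)
        if unknown:
            raise KeyError(f"unknown nodes: {sorted(unknown)}")
        kept_nodes = [v for v in self._adj if v in keep]
        kept_edges = [(u, v) for u, v in self.edges if u in keep and v in keep]
        return Graph(edges=kept_edges, nodes=kept_nodes)

    def __contains__(self, v: object) -> bool:
        return v in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return set(self._adj) == set(other._adj) and set(self.edges) == set(other.edges)

    def __hash__(self) -> int:  # pragma: no cover - not used as dict key
        return hash((frozenset(self._adj), frozenset(self.edges)))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class NodeDistance:
    """Hop distances from ``source``; unreachable nodes are absent."""

    source: str
    dist: Mapping[str, int]


@dataclass(frozen=True)
class GeodesicCounts:
    """Shortest-path counts for every ordered reachable pair.

    ``sigma[(s, t)]`` is the number of distinct shortest s-t paths;
    ``sigma_through[(s, t, v)]`` the number of those with interior node v
    (zero-valued triples are omitted; use :meth:`through`).
    """

    sigma: Mapping[tuple[str, str], int]
    sigma_through: Mapping[tuple[str, str, str], int] = field(default_factory=dict)

    def count(self, s: str, t: str) -> int:
        return self.sigma.get((s, t), 0)

    def through(self, s: str, t: str, v: str) -> int:
        return self.sigma_through.get((s, t, v), 0)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


class GMLParseError(ValueError):
    """Raised on malformed GML input; message names the offending line."""


def _tokenize_gml(text: str) -> list[tuple[int, str]]:
    tokens: list[tuple[int, str]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        i = 0
        while i < len(line):
            c = line[i]
            if c.isspace():
                i += 1
            elif c == "#":
                break
            elif c in "[]":
                tokens.append((ln, c))
                i += 1
            elif c == '"':
                j = line.find('"', i + 1)
                if j < 0:
                    raise GMLParseError(f"line {ln}: unterminated string")
                tokens.append((ln, line[i : j + 1]))
                i = j + 1
            else:
                j = i
                while j < len(line) and not line[j].isspace() and line[j] not in '[]#"':
                    j += 1
                tokens.append((ln, line[i:j]))
                i = j
    return tokens


def _gml_scalar(tok: str) -> int | float | str:
    if tok.startswith('"') and tok.endswith('"'):
        return tok[1:-1]
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        return tok


def _parse_gml_pairs(tokens, pos, depth):
    pairs: list[tuple[str, object]] = []
    while pos < len(tokens):
        ln, tok = tokens[pos]
        if tok == "]":
            if depth == 0:
                raise GMLParseError(f"line {ln}: unexpected ']'")
            return pairs, pos + 1
        if tok == "[":
            raise GMLParseError(f"line {ln}: '[' without a preceding key")
        key = tok
        pos += 1
        if pos >= len(tokens):
            raise GMLParseError(f"line {ln}: key {key!r} has no value")
        vln, vtok = tokens[pos]
        if vtok == "[":
            sub, pos = _parse_gml_pairs(tokens, pos + 1, depth + 1)
            pairs.append((key, sub))
        else:
            if vtok == "]":
                raise GMLParseError(f"line {vln}: key {key!r} has no value")
            pairs.append((key, _gml_scalar(vtok)))
            pos += 1
    if depth:
        raise GMLParseError("unexpected end of input: unclosed '['")
    return pairs, pos


def read_gml(text: str) -> Graph:
    """Parse a GML document (graph/node/edge subset) into a :class:`Graph`.

    Node identity is the ``label`` when present, else the stringified ``id``.
    Directed flags, reciprocal or duplicate edges and self-loops are collapsed
    to undirected simple edges with a logged warning.
    """
    tokens = _tokenize_gml(text)
    pairs, _ = _parse_gml_pairs(tokens, 0, 0)
    graph_block = next((v for k, v in pairs if k == "graph" and isinstance(v, list)), None)
    if graph_block is None:
        raise GMLParseError("no 'graph [ ... ]' block found")

    directed = any(k == "directed" and v == 1 for k, v in graph_block)
    id_to_label: dict[str, str] = {}
    nodes: list[str] = []
    raw_edges: list[tuple[str, str]] = []
    for key, val in graph_block:
        if key == "node":
            if not isinstance(val, list):
                raise GMLParseError("node record is not a block")
            attrs = dict(val)
            if "id" not in attrs:
                raise GMLParseError("node record without id")
            nid = str(attrs["id"])
            if nid in id_to_label:
                raise GMLParseError(f"duplicate node id {nid}")
            label = str(attrs.get("label", nid))
            id_to_label[nid] = label
            nodes.append(label)
        elif key == "edge":
            if not isinstance(val, list):
                raise GMLParseError("edge record is not a block")
            attrs = dict(val)
            if "source" not in attrs or "target" not in attrs:
                raise GMLParseError("edge record without source/target")
            raw_edges.append((str(attrs["source"]), str(attrs["target"])))

    edges: set[tuple[str, str]] = set()
    n_loops = n_dups = 0
    for s, t in raw_edges:
        if s not in id_to_label or t not in id_to_label:
            missing = s if s not in id_to_label else t
            raise GMLParseError(f"edge references unknown node id {missing}")
        u, v = id_to_label[s], id_to_label[t]
        if u == v:
            n_loops += 1
            continue
        e = (u, v) if u < v else (v, u)
        if e in edges:
            n_dups += 1
        edges.add(e)
    if directed:
        logger.warning("GML input flagged directed; collapsing to undirected edges")
    if n_loops:
        logger.warning("dropped %d self-loop(s) from GML input", n_loops)
    if n_dups:
        logger.warning("collapsed %d duplicate/reciprocal edge(s) from GML input", n_dups)
    return Graph(edges=sorted(edges), nodes=nodes)


def read_edge_list(text: str) -> Graph:
    """Parse a whitespace edge list; '#' lines are comments.

    A single-token line declares an isolated node; two tokens declare an edge.
    Duplicate and reversed edges collapse to one undirected edge.
    """
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) == 1:
            nodes.append(parts[0])
        elif len(parts) == 2:
            if parts[0] == parts[1]:
                logger.warning("line %d: dropped self-loop on %r", ln, parts[0])
                nodes.append(parts[0])
            else:
                edges.append((parts[0], parts[1]))
        else:
            raise ValueError(f"line {ln}: expected 1 or 2 tokens, got {len(parts)}")
    return Graph(edges=edges, nodes=nodes)


# ---------------------------------------------------------------------------
# Shortest-path primitives
# ---------------------------------------------------------------------------


def bfs_distances(g: Graph, source: str) -> NodeDistance:
    """Exact hop distances from ``source``; unreachable nodes are omitted."""
    if source not in g:
        raise KeyError(f"unknown source node {source!r}")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return NodeDistance(source=source, dist=dist)


def count_geodesics(g: Graph) -> GeodesicCounts:
    """Shortest-path counts for all ordered pairs, via per-source BFS DAGs.

    sigma_through is derived from the composition rule: v lies on a shortest
    s-t path iff d(s,v) + d(v,t) = d(s,t), contributing sigma(s,v)*sigma(v,t).
    Quadratic storage — intended for small graphs and oracle checks.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    nodes = g.nodes
    dist: dict[str, dict[str, int]] = {}
    paths: dict[str, dict[str, int]] = {}
    for s in nodes:
        d = {s: 0}
        np_ = {s: 1}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in g.neighbors(v):
                if w not in d:
                    d[w] = d[v] + 1
                    np_[w] = 0
                    queue.append(w)
                if d[w] == d[v] + 1:
                    np_[w] += np_[v]
        dist[s] = d
        paths[s] = np_

    sigma: dict[tuple[str, str], int] = {}
    through: dict[tuple[str, str, str], int] = {}
    for s in nodes:
        for t, cnt in paths[s].items():
            sigma[(s, t)] = cnt
    for s in nodes:
        for t in paths[s]:
            if s == t:
                continue
            dst = dist[s][t]
            for v in paths[s]:
                if v in (s, t) or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dst:
                    through[(s, t, v)] = paths[s][v] * paths[v][t]
    return GeodesicCounts(sigma=sigma, sigma_through=through)


def connected_components(g: Graph) -> list[list[str]]:
    """Connected components as node lists, in insertion order of discovery."""
    seen: set[str] = set()
    comps: list[list[str]] = []
    for v in g.nodes:
        if v in seen:
            continue
        comp = [v]
        seen.add(v)
        queue = deque([v])
        while queue:
            u = queue.popleft()
            for w in g.neighbors(u):
                if w not in seen:
                    seen.add(w)
                    comp.append(w)
                    queue.append(w)
        comps.append(comp)
    return comps


def largest_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest node label.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    comps = connected_components(g)
    best_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == best_size), key=min)
    return g.subgraph(best)


# ---------------------------------------------------------------------------
# Annotated GML export
# ---------------------------------------------------------------------------

_GML_ATTRS = {
    "degree": "degree_c",
    "betweenness": "betweenness_c",
    "closeness": "closeness_c",
    "eccentricity": "eccentricity",
    "eigenvector": "eigenvector_c",
}


def write_annotated_gml(g: Graph, profile) -> str:
    """Serialize ``g`` with the five per-node scores as numeric attributes.

    The result is plain GML, round-trippable by :func:`read_gml` (the score
    attributes are ignored on read).  Numbers carry 12 significant digits.
    Nodes outside the component on which a restricted measure was computed
    get attribute value 0.
    """
    vectors = profile.vectors
    full = set(vectors["degree"].scores)
    if full != set(g.nodes):
        raise ValueError("profile does not cover the node set of the graph")
    lines = ["graph [", "  directed 0"]
    index = {v: i for i, v in enumerate(g.nodes)}
    for v in g.nodes:
        lines.append("  node [")
        lines.append(f"    id {index[v]}")
        lines.append(f'    label "{v}"')
        for measure, attr in _GML_ATTRS.items():
            val = vectors[measure].scores.get(v, 0.0)
            lines.append(f"    {attr} {round_sig(float(val)):.12g}")
        lines.append("  ]")
    for u, v in g.edges:
        lines.append(f"  edge [ source {index[u]} target {index[v]} ]")
    lines.append("]")
    return "\n".join(lines) + "\n"
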