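"""Random baseline and planted-structure network generators, plus fixtures.

The planted generators carry machine-readable ground truth (the node set
known to be influential by construction), so ranking stages can be scored
without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .graph import Graph, read_edge_list, read_gml

logger = logging.getLogger(__name__)

FIXTURE_NAMES = ("karate", "dolphins", "celegans")

__all__ = [
    "ERParameters",
    "AnnotatedGraph",
    "FixtureUnavailableError",
    "FIXTURE_NAMES",
    "erdos_renyi",
    "planted_hub",
    "planted_bridge",
    "bundled_fixture",
]


@dataclass(frozen=True)
class ERParameters:
    """G(n, p): n nodes, each of the C(n,2) pairs linked with probability p."""

    n: int
    p: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class AnnotatedGraph:
    """A graph plus its documented/constructed influential node set.

    ``influential`` may be empty only for datasets whose sources name no
    key nodes; generators always plant a non-empty set.
    """

    graph: Graph
    influential: frozenset
    construction: str

    def __post_init__(self) -> None:
        unknown = set(self.influential) - set(self.graph.nodes)
        if unknown:
            raise ValueError(f"influential nodes not in graph: {sorted(unknown)}")


def erdos_renyi(params: ERParameters) -> Graph:
    """Seeded G(n, p) draw with node labels "1".."n".

    Candidate pairs are enumerated in a fixed (i < j, numeric) order and
    decided by one vectorized uniform draw, so a seed pins the edge set on
    any platform.
    """
    n, p = params.n, params.p
    rng = np.random.default_rng(params.seed)
    pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
    if pairs:
        keep = rng.random(len(pairs)) < p
        edges = [(str(i), str(j)) for (i, j), k in zip(pairs, keep) if k]
    else:
        edges = []
    return Graph(edges=edges, nodes=[str(i) for i in range(1, n + 1)])


def planted_hub(n_spokes: int, rewire: float = 0.1, seed: int = 0) -> AnnotatedGraph:
    """A star whose spokes carry a sparse random ring; the hub is the target.

    Each consecutive spoke pair (around the ring) is linked with probability
    ``rewire``, so spoke degree never exceeds 3 and the hub keeps a strict
    degree lead for any rewire < 1.
    """
    if n_spokes < 3:
        raise ValueError("n_spokes must be >= 3")
    if not 0.0 <= rewire <= 1.0:
        raise ValueError("rewire must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hub = "hub"
    spokes = [f"s{i}" for i in range(1, n_spokes + 1)]
    edges = [(hub, s) for s in spokes]
    ring = [(spokes[i], spokes[(i + 1) % n_spokes]) for i in range(n_spokes)]
    keep = rng.random(len(ring)) < rewire
    edges += [e for e, k in zip(ring, keep) if k]
    g = Graph(edges=edges, nodes=[hub] + spokes)
    return AnnotatedGraph(
        graph=g,
        influential=frozenset({hub}),
        construction=f"planted_hub(n_spokes={n_spokes}, rewire={rewire}, seed={seed})",
    )


def planted_bridge(clique_size: int, seed: int = 0) -> AnnotatedGraph:
    """Two cliques joined only through a degree-2 broker node.

    Every cross-clique shortest path runs through the broker, making it the
    unique betweenness maximum while its degree stays 2.
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    left = [f"a{i}" for i in range(1, clique_size + 1)]
    right = [f"b{i}" for i in range(1, clique_size + 1)]
    broker = "broker"
    edges = [(u, v) for part in (left, right) for i, u in enumerate(part) for v in part[i + 1 :]]
    edges += [(broker, left[0]), (broker, right[0])]
    g = Graph(edges=edges, nodes=left + [broker] + right)
    return AnnotatedGraph(
        graph=g,
        influential=frozenset({broker}),
        construction=f"planted_bridge(clique_size={clique_size}, seed={seed})",
    )


class FixtureUnavailableError(FileNotFoundError):
    """A published dataset is known to this package but not redistributed."""


_FIXTURE_FILES = {
    "karate": "karate.edgelist",
    "dolphins": "dolphins.edgelist",
    "celegans": "celegans.gml",
}

# Documented key nodes from the originating field studies: the karate club's
# instructor (node 1) and president (node 34); the dolphins singled out in
# published analyses.  The C. elegans source names no individual neurons.
_FIXTURE_TRUTH = {
    "karate": frozenset({"1", "34"}),
    "dolphins": frozenset({"Grin", "SN100"}),
    "celegans": frozenset(),
}


def _fixture_text(filename: str) -> str:
    ref = resources.files("cenval").joinpath("data", filename)
    if not ref.is_file():
        raise FixtureUnavailableError(
            f"dataset file {filename!r} is not bundled with this distribution "
            "(it could not be redistributed); download the public copy and "
            f"place it at <package>/data/{filename} to enable this fixture"
        )
    return ref.read_text()


def bundled_fixture(name: str) -> AnnotatedGraph:
    """Load one of the vendored study networks with its ground-truth nodes.

    karate    34 nodes / 78 edges, influential = {"1", "34"}
    dolphins  62 nodes / 159 edges, influential = {"Grin", "SN100"}
    celegans  297 nodes / 2359 edges, influential = {} (none documented)

    Raises :class:`FixtureUnavailableError` when the underlying data file is
    not present in the package data directory.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
    text = _fixture_text(_FIXTURE_FILES[name])
    if _FIXTURE_FILES[name].endswith(".gml"):
        g = read_gml(text)
    else:
        g = read_edge_list(text)
    if name == "celegans":
        logger.warning("celegans fixture carries no documented influential nodes")
    return AnnotatedGraph(
        graph=g,
        influential=_FIXTURE_TRUTH[name],
        construction=f"fixture:{name}",
    )
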