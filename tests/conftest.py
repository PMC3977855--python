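import pytest

from cenval import ERParameters, Graph, bundled_fixture, erdos_renyi


@pytest.fixture(scope="session")
def karate():
    return bundled_fixture("karate")


@pytest.fixture
def path3():
    return Graph(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def k4():
    names = ["a", "b", "c", "d"]
    return Graph(edges=[(u, v) for i, u in enumerate(names) for v in names[i + 1 :]])


@pytest.fixture
def c4():
    return Graph(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])


@pytest.fixture
def star5():
    """K1,4: hub h with four leaves."""
    return Graph(edges=[("h", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def random_graph():
    """Factory for seeded G(n, p) samples."""

    def make(n: int, p: float, seed: int) -> Graph:
        return erdos_renyi(ERParameters(n=n, p=p, seed=seed))

    return make


def connected(g: Graph) -> bool:
    from cenval import largest_connected_component

    return g.n > 0 and largest_connected_component(g).n == g.n


@pytest.fixture
def random_connected_graph(random_graph):
    """Factory: first connected G(n, p) sample at or after the given seed."""

    def make(n: int, p: float, seed: int) -> Graph:
        for s in range(seed, seed + 500):
            g = random_graph(n, p, s)
            if connected(g):
                return g
        raise RuntimeError("no connected sample found")

    return make
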