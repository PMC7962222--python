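import numpy as np
import pytest

import rsmine as rm


@pytest.fixture(scope="session")
def toy():
    """The self-checked four-graph toy dataset over {A, B, C, D}."""
    return rm.toy_fixture()


@pytest.fixture(scope="session")
def five_edge_graph():
    """A 5-edge graph whose search states exercise every valid/invalid case.

    Edge ids by lexicographic endpoint order:
    e1=(a,b), e2=(a,c), e3=(b,c), e4=(b,d), e5=(c,d).
    """
    return rm.SingleGraph.from_label_pairs(
        [("a", "b"), ("a", "c"), ("b", "c"), ("b", "d"), ("c", "d")]
    )


@pytest.fixture(scope="session")
def triangle():
    return rm.SingleGraph.from_label_pairs([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture(scope="session")
def path3():
    return rm.SingleGraph.from_label_pairs([("a", "b"), ("b", "c"), ("c", "d")])


def random_graph(seed, max_vertices=8, edge_prob=0.5, max_edges=12):
    """Seeded random simple graph with at most ``max_edges`` edges (or None)."""
    rng = np.random.default_rng(seed)
    nv = int(rng.integers(3, max_vertices))
    pairs = [
        (f"v{a}", f"v{b}")
        for a in range(nv)
        for b in range(a + 1, nv)
        if rng.random() < edge_prob
    ]
    if not pairs:
        return None
    g = rm.SingleGraph.from_label_pairs(pairs)
    return g if g.n_edges <= max_edges else None
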