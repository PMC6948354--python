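import networkx as nx
import numpy as np
import pytest

from netpharm import StudyParams, generate_study


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests."""
    return generate_study(1, StudyParams())


@pytest.fixture
def random_graph_factory():
    """Seeded Erdos-Renyi graphs with string labels, possibly disconnected."""

    def make(seed: int, n_max: int = 25, p: float | None = None) -> nx.Graph:
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.05, 0.6)) if p is None else p
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})

    return make


def write_tsv(path, header: str, rows):
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(row + "\n")
    return path
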