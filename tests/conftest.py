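import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ccdriver.pipeline import run_fixture_study
from ccdriver.simulate import SimulationConfig

STUDY_GROUPS = (("GV_start", 3), ("MII_end", 3), ("GV_end", 3))


def random_graph(rng: np.random.Generator, n_max: int = 8, p: float | None = None) -> nx.Graph:
    """Erdos-Renyi graph with string labels, 2..n_max nodes."""
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.15, 0.7))
    g = nx.Graph()
    labels = [f"n{i}" for i in range(n)]
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g


def edge_set(g: nx.Graph) -> set:
    return {tuple(sorted(e)) for e in g.edges()}


@pytest.fixture(scope="session")
def study_run():
    """One full fixture-study pipeline run (seed 1), shared across tests."""
    cfg = SimulationConfig(groups=STUDY_GROUPS, seed=1)
    bundle, report = run_fixture_study(cfg)
    return bundle, report
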