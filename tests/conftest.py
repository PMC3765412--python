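import numpy as np
import pytest

from grank import assign_depths, build_pog, figure1_fixture
from grank.model import GoGraph, Relation, Term


@pytest.fixture(scope="session")
def bundle():
    return figure1_fixture()


@pytest.fixture(scope="session")
def fixture_pog(bundle):
    return build_pog(bundle.graph)


@pytest.fixture(scope="session")
def fixture_depths(bundle):
    return assign_depths(bundle.graph)


def random_typed_dag(seed: int, n_max: int = 12, p_edge: float = 0.35,
                     p_isa: float = 0.6) -> GoGraph:
    """Random typed DAG: edges only from higher to lower index, hence acyclic."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    terms = [Term(f"T{i:02d}", f"node {i}", "sim") for i in range(n)]
    edges = []
    for child in range(1, n):
        for parent in range(child):
            if rng.random() < p_edge:
                rel = Relation.IS_A if rng.random() < p_isa else Relation.PART_OF
                edges.append((f"T{child:02d}", f"T{parent:02d}", rel))
    return GoGraph(terms, edges)
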