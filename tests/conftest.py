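import networkx as nx
import pytest

from moonnet.io_formats import ClusterSystem
from moonnet.ontology import AnnotationMap, build_dag
from moonnet.synthetic import ScenarioParams, generate_scenario


@pytest.fixture
def bowtie() -> nx.Graph:
    """Two triangles sharing node c: a-b-c and c-d-e."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"),
                      ("c", "d"), ("c", "e"), ("d", "e")])
    return g


@pytest.fixture
def bowtie_system() -> ClusterSystem:
    return ClusterSystem([frozenset("abc"), frozenset("cde")])


@pytest.fixture
def chain_dag():
    """T3 is_a T2 is_a T1 (root)."""
    return build_dag({"T1": [], "T2": ["T1"], "T3": ["T2"]}, root="T1")


@pytest.fixture
def diamond_dag():
    """T4 is_a {T2, T3}; T2, T3 is_a T1 (root)."""
    return build_dag(
        {"T1": [], "T2": ["T1"], "T3": ["T1"], "T4": ["T2", "T3"]}, root="T1"
    )


@pytest.fixture
def flat_dag():
    """Root plus independent leaf terms Ta..Te."""
    return build_dag(
        {"R": [], "Ta": ["R"], "Tb": ["R"], "Tc": ["R"], "Td": ["R"],
         "Te": ["R"]},
        root="R",
    )


def make_annotations(dag, direct: dict) -> AnnotationMap:
    return AnnotationMap(
        direct={p: frozenset(ts) for p, ts in direct.items()}, dag=dag
    )


@pytest.fixture(scope="session")
def easy_scenario():
    """Default planted scenario (3 clique modules of 20, 2 shared nodes)."""
    return generate_scenario(ScenarioParams(seed=0))


@pytest.fixture(scope="session")
def easy_pipeline(easy_scenario):
    """Full pipeline result on the default scenario (computed once)."""
    from moonnet.pipeline import detect_from_inputs

    return detect_from_inputs(
        easy_scenario.network, easy_scenario.annotations, easy_scenario.dag
    )
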