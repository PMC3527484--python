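import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from traitnet.synthetic_data import (
    SynthConfig,
    generate_planted_scores,
    six_node_reference_graph,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def cluster_graph6() -> nx.Graph:
    return six_node_reference_graph()


@pytest.fixture
def two_cliques_bridge() -> nx.Graph:
    from traitnet.synthetic_data import generate_benchmark_graph

    return generate_benchmark_graph("two_cliques_bridge", k=4)


@pytest.fixture(scope="session")
def small_planted():
    """3 factors x 2 facets x 4 items, 300 subjects: quick, well-separated."""
    cfg = SynthConfig(
        n_subjects=300,
        n_factors=3,
        facets_per_factor=2,
        items_per_facet=4,
        loading_range=(0.6, 0.8),
        noise_sd=0.5,
        seed=7,
    )
    return generate_planted_scores(cfg)
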