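"""Shared fixtures: small hand-checkable networks and a compact synthetic cohort."""

import networkx as nx
import pytest

from netcog import RosterSurveyWave, SyntheticConfig, build_network
from netcog import generate_ground_truth, generate_longitudinal_network

#: compact cohort used wherever tests need a realistic wave network quickly
SMALL_COHORT = SyntheticConfig(
    n_subjects=60, n_blocks=3, p_in=0.35, p_out=0.03, n_waves=3,
    churn_drop=(0.3, 0.1), seed=1,
)


def _graph(edges, nodes=None, wave_id=1):
    g = nx.Graph(wave_id=wave_id)
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture(scope="session")
def small_cohort():
    truths = generate_ground_truth(SMALL_COHORT)
    networks, blocks = generate_longitudinal_network(SMALL_COHORT, truths)
    return {"config": SMALL_COHORT, "truths": truths, "networks": networks, "blocks": blocks}


@pytest.fixture(scope="session")
def planted_strong():
    """Strongly separated planted partition: 4 blocks x 20, p_in=0.5, p_out=0.01."""
    cfg = SyntheticConfig(
        n_subjects=80, n_blocks=4, p_in=0.5, p_out=0.01, n_waves=2,
        churn_drop=(0.1,), seed=1,
    )
    truths = generate_ground_truth(cfg)
    networks, blocks = generate_longitudinal_network(cfg, truths)
    return {"config": cfg, "truths": truths, "networks": networks, "blocks": blocks}


@pytest.fixture
def triangle():
    return _graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star7():
    """Hub H with six leaves."""
    return _graph([("H", f"L{i}") for i in range(6)])


@pytest.fixture
def roster_small():
    """Six-subject roster with nine friend nominations, three reciprocated."""
    records = [
        ("A", "B", "friend"), ("B", "A", "friend"),          # mutual
        ("C", "D", "friend"), ("D", "C", "friend"),          # mutual
        ("E", "F", "friend"), ("F", "E", "friend"),          # mutual
        ("A", "C", "friend"),                                 # one-sided
        ("B", "E", "friend"),                                 # one-sided
        ("D", "F", "friend"),                                 # one-sided
        ("C", "A", "acquaintance"),
        ("E", "B", "recognize"),
        ("F", "D", "unknown"),
    ]
    return RosterSurveyWave(wave_id=3, records=records)


@pytest.fixture
def two_wave_nets():
    """Hand-built pair of waves sharing some edges: Jaccard = 1/3."""
    early = _graph([("A", "B"), ("B", "C")], wave_id=1)
    late = _graph([("A", "B"), ("C", "D")], nodes=["A", "B", "C", "D"], wave_id=2)
    return early, late
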