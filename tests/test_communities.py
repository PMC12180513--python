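"""Consensus community detection: base partitions, meet, meso ties, overlap."""

import itertools

import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from netcog import (
    ConsensusConfig,
    Partition,
    consensus_communities,
    meso_ties,
    run_base_partitions,
    tie_overlap_stats,
)
from netcog.communities import ALGORITHMS, CommunityDetectionError
from netcog.experiments import consensus_recovery_ari


def _partition(assignment, algorithm="map_equation"):
    return Partition(algorithm=algorithm, assignment=dict(assignment))


def two_cliques_bridge():
    g = nx.Graph()
    left = [f"l{i}" for i in range(8)]
    right = [f"r{i}" for i in range(8)]
    for group in (left, right):
        g.add_edges_from(itertools.combinations(group, 2))
    g.add_edge("l0", "r0")
    return g, set(left), set(right)


class TestBasePartitions:
    def test_two_cliques_found_by_all_algorithms(self):
        g, left, right = two_cliques_bridge()
        partitions = run_base_partitions(g, ConsensusConfig(seed=1))
        assert set(partitions) == set(ALGORITHMS)
        for p in partitions.values():
            cells = {}
            for node, label in p.assignment.items():
                cells.setdefault(label, set()).add(node)
            assert set(map(frozenset, cells.values())) == {
                frozenset(left), frozenset(right)
            }, p.algorithm

    def test_complete_graph_is_one_community(self):
        g = nx.complete_graph(12)
        for p in run_base_partitions(g, ConsensusConfig(seed=1)).values():
            assert len(set(p.assignment.values())) == 1, p.algorithm

    def test_planted_partition_recovered_by_each_algorithm(self, planted_strong):
        # 4 blocks x 20 nodes at strong in/out contrast
        net, blocks = planted_strong["networks"][0], planted_strong["blocks"]
        for p in run_base_partitions(net, ConsensusConfig(seed=1)).values():
            nodes = sorted(p.assignment)
            ari = adjusted_rand_score(
                [blocks[v] for v in nodes], [p.assignment[v] for v in nodes]
            )
            assert ari == 1.0, p.algorithm

    def test_partitions_cover_all_nodes_and_are_seeded(self, small_cohort):
        net = small_cohort["networks"][0]
        a = run_base_partitions(net, ConsensusConfig(seed=3))
        b = run_base_partitions(net, ConsensusConfig(seed=3))
        for alg in ALGORITHMS:
            assert set(a[alg].assignment) == set(net.nodes())
            assert a[alg].assignment == b[alg].assignment

    def test_edgeless_network_raises_labeled_error(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        with pytest.raises(CommunityDetectionError, match="no edges"):
            run_base_partitions(g)


class TestConsensusMeet:
    def test_min_size_filter(self):
        assignment = {f"x{i}": 0 for i in range(6)} | {f"y{i}": 1 for i in range(4)}
        parts = [_partition(assignment, a) for a in ALGORITHMS]
        consensus = consensus_communities(parts, min_size=5)
        assert consensus.communities == [frozenset(f"x{i}" for i in range(6))]
        assert consensus.unassigned == frozenset(f"y{i}" for i in range(4))

    def test_label_invariance(self):
        base = {f"x{i}": 0 for i in range(5)} | {f"y{i}": 1 for i in range(5)}
        relabeled = {node: 9 - label for node, label in base.items()}
        parts = [
            _partition(base, "map_equation"),
            _partition(relabeled, "edge_betweenness"),
            _partition(base, "modularity_opt"),
            _partition(relabeled, "random_walk"),
        ]
        consensus = consensus_communities(parts, min_size=5)
        assert set(consensus.communities) == {
            frozenset(f"x{i}" for i in range(5)),
            frozenset(f"y{i}" for i in range(5)),
        }

    def test_overlapping_cells_reduce_to_common_core(self):
        # algorithms agree on a 7-node core; three fringe nodes split differently
        core = {f"c{i}" for i in range(7)}
        fringe = {"f0", "f1", "f2"}
        nodes = core | fringe
        parts = []
        for k, alg in enumerate(ALGORITHMS):
            assignment = {n: 0 for n in core}
            # hand-enumerated meet: each fringe node isolated by some pair of
            # partitions, so every meet cell containing fringe nodes is small
            for j, n in enumerate(sorted(fringe)):
                assignment[n] = 0 if (j + k) % 2 else 1
            parts.append(_partition(assignment, alg))
        consensus = consensus_communities(parts, min_size=5)
        assert consensus.communities == [frozenset(core)]
        assert consensus.unassigned == frozenset(fringe)

    def test_meet_matches_brute_force_enumeration(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = run_base_partitions(net, ConsensusConfig(seed=2))
        consensus = consensus_communities(parts, min_size=5)
        # brute force: group nodes by their 4-tuple of labels
        cells = {}
        for node in net.nodes():
            key = tuple(parts[a].assignment[node] for a in parts)
            cells.setdefault(key, set()).add(node)
        expected = {frozenset(c) for c in cells.values() if len(c) >= 5}
        assert set(consensus.communities) == expected
        leftovers = set(net.nodes()) - set().union(set(), *expected)
        assert consensus.unassigned == frozenset(leftovers)

    def test_consensus_contained_in_every_base_partition(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = run_base_partitions(net, ConsensusConfig(seed=4))
        consensus = consensus_communities(parts, min_size=5)
        for community in consensus.communities:
            for p in parts.values():
                labels = {p.assignment[n] for n in community}
                assert len(labels) == 1

    def test_unassigned_monotone_in_min_size(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = run_base_partitions(net, ConsensusConfig(seed=5))
        sizes = [2, 3, 5, 8, 12]
        unassigned = [
            len(consensus_communities(parts, min_size=m).unassigned) for m in sizes
        ]
        assert unassigned == sorted(unassigned)

    def test_mismatched_node_sets_rejected(self):
        a = _partition({"x": 0, "y": 0}, "map_equation")
        b = _partition({"x": 0, "z": 0}, "random_walk")
        with pytest.raises(ValueError, match="different node set"):
            consensus_communities([a, b], min_size=1)

    def test_order_invariance_of_partitions(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = list(run_base_partitions(net, ConsensusConfig(seed=6)).values())
        forward = consensus_communities(parts, min_size=5)
        backward = consensus_communities(parts[::-1], min_size=5)
        assert set(forward.communities) == set(backward.communities)
        assert forward.unassigned == backward.unassigned

    def test_planted_blocks_recovered_exactly(self, small_cohort):
        net, blocks = small_cohort["networks"][0], small_cohort["blocks"]
        parts = run_base_partitions(net, ConsensusConfig(seed=1))
        consensus = consensus_communities(parts, min_size=5)
        assert consensus_recovery_ari(consensus, blocks) == 1.0


class TestMesoTies:
    def test_same_community_pair_is_tie(self):
        assignment = {f"x{i}": 0 for i in range(5)} | {f"y{i}": 1 for i in range(5)}
        consensus = consensus_communities(
            [_partition(assignment, a) for a in ALGORITHMS], min_size=5
        )
        ties = meso_ties(consensus)
        assert ties.tie("x0", "x1") == 1
        assert ties.tie("x0", "y0") == 0

    def test_unassigned_member_never_ties(self):
        assignment = {f"x{i}": 0 for i in range(5)} | {"u1": 1, "u2": 1}
        consensus = consensus_communities(
            [_partition(assignment, a) for a in ALGORITHMS], min_size=5
        )
        ties = meso_ties(consensus)
        assert ties.tie("x0", "u1") == 0
        assert ties.tie("u1", "u2") == 0  # two unassigned nodes never share

    def test_positive_pair_count_two_communities_of_five(self):
        assignment = {f"x{i}": 0 for i in range(5)} | {f"y{i}": 1 for i in range(5)}
        consensus = consensus_communities(
            [_partition(assignment, a) for a in ALGORITHMS], min_size=5
        )
        assert len(meso_ties(consensus).positive_pairs()) == 20  # 2 * C(5,2)


class TestTieOverlap:
    def test_micro_subset_of_meso(self):
        g = nx.Graph([("x0", "x1"), ("x2", "x3")])
        g.add_nodes_from(f"x{i}" for i in range(5))
        assignment = {f"x{i}": 0 for i in range(5)}
        consensus = consensus_communities(
            [_partition(assignment, a) for a in ALGORITHMS], min_size=5
        )
        overlap = tie_overlap_stats(g, meso_ties(consensus))
        assert overlap.micro_also_meso == 1.0
        assert overlap.meso_also_micro == 2 / 10

    def test_disjoint_micro_and_meso(self):
        assignment = {f"x{i}": 0 for i in range(5)} | {f"y{i}": 1 for i in range(5)}
        g = nx.Graph([("x0", "y0"), ("x1", "y1")])  # only cross-community edges
        g.add_nodes_from(assignment)
        consensus = consensus_communities(
            [_partition(assignment, a) for a in ALGORITHMS], min_size=5
        )
        overlap = tie_overlap_stats(g, meso_ties(consensus))
        assert overlap.micro_also_meso == 0.0
        assert overlap.meso_also_micro == 0.0

    def test_matches_brute_force_pair_enumeration(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = run_base_partitions(net, ConsensusConfig(seed=1))
        consensus = consensus_communities(parts, min_size=5)
        ties = meso_ties(consensus)
        overlap = tie_overlap_stats(net, ties)
        micro = meso = both = 0
        for a, b in itertools.combinations(sorted(net.nodes()), 2):
            is_micro = net.has_edge(a, b)
            is_meso = ties.tie(a, b) == 1
            micro += is_micro
            meso += is_meso
            both += is_micro and is_meso
        assert (overlap.n_micro, overlap.n_meso, overlap.n_both) == (micro, meso, both)
        assert overlap.micro_also_meso == both / micro
        assert overlap.meso_also_micro == both / meso
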