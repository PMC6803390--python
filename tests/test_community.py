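"""Community detection, label alignment, bootstrap memberships, consensus."""

import networkx as nx
import numpy as np
import pytest

from interactoscope.community import (
    AlgorithmSpec,
    Partition,
    UnavailableAlgorithm,
    adjusted_agreement,
    align_partitions,
    bootstrap_memberships,
    consensus_partition,
    detect_communities,
)
from interactoscope.synthetic_data import planted_partition_graph


class TestDetectCommunities:
    @pytest.mark.parametrize("algo", ["walktrap", "spinglass", "infomap"])
    def test_two_cliques_split_cleanly(self, two_cliques, algo):
        g, left, right = two_cliques
        part = detect_communities(g, AlgorithmSpec(algo, seed=5))
        assert part.n_communities == 2
        assert set(map(frozenset, part.communities().values())) == {frozenset(left), frozenset(right)}

    def test_complete_graph_is_one_community(self):
        part = detect_communities(nx.complete_graph(6), AlgorithmSpec("walktrap", seed=0))
        assert part.n_communities == 1

    @pytest.mark.parametrize("algo", ["walktrap", "infomap"])
    def test_planted_blocks_recovered(self, algo):
        net, truth = planted_partition_graph(60, 3, 0.5, 0.01, seed=1)
        part = detect_communities(net, AlgorithmSpec(algo, seed=9))
        assert adjusted_agreement(part, truth.partition) >= 0.9

    def test_stochastic_algorithms_reproducible_for_fixed_seed(self):
        net, _ = planted_partition_graph(40, 2, 0.4, 0.03, seed=4)
        a = detect_communities(net, AlgorithmSpec("spinglass", seed=17))
        b = detect_communities(net, AlgorithmSpec("spinglass", seed=17))
        assert a.membership == b.membership

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            AlgorithmSpec("louvainish")

    def test_sbm_backend_reported_unavailable(self, two_cliques):
        g, _, _ = two_cliques
        with pytest.raises(UnavailableAlgorithm):
            detect_communities(g, AlgorithmSpec("sbm"))


def test_partition_requires_contiguous_ids():
    with pytest.raises(ValueError, match="contiguous"):
        Partition({"A": 1, "B": 3})


class TestAlignPartitions:
    def test_label_permutation_recovered(self):
        ref = Partition({"A": 1, "B": 1, "C": 2, "D": 2, "E": 3})
        other = Partition({"A": 3, "B": 3, "C": 1, "D": 1, "E": 2})
        assert align_partitions(ref, other).membership == ref.membership

    def test_greedy_maximum_overlap(self):
        ref = Partition({"A": 1, "B": 1, "C": 2, "D": 2})
        other = Partition({"A": 1, "B": 1, "C": 1, "D": 2})
        aligned = align_partitions(ref, other)
        # other's big community overlaps ref community 1 most
        assert aligned.membership["A"] == aligned.membership["B"] == aligned.membership["C"] == 1
        assert aligned.membership["D"] == 2

    def test_identity(self):
        ref = Partition({"A": 1, "B": 2})
        assert align_partitions(ref, ref).membership == ref.membership

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            align_partitions(Partition({"A": 1}), Partition({"B": 1}))

    def test_alignment_never_changes_grouping(self):
        rng = np.random.default_rng(0)
        nodes = [f"G{i}" for i in range(20)]
        for _ in range(25):
            ref = Partition.from_groups(_random_groups(nodes, rng))
            other = Partition.from_groups(_random_groups(nodes, rng))
            aligned = align_partitions(ref, other)
            assert adjusted_agreement(aligned, other) == pytest.approx(1.0)


def _random_groups(nodes, rng):
    k = int(rng.integers(1, 5))
    labels = rng.integers(0, k, size=len(nodes))
    groups = {}
    for v, l in zip(nodes, labels):
        groups.setdefault(int(l), set()).add(v)
    return list(groups.values())


class TestBootstrapMemberships:
    def test_no_resample_single_boot_is_one_hot_reference(self, two_cliques):
        g, _, _ = two_cliques
        spec = AlgorithmSpec("walktrap", seed=1)
        ref = detect_communities(g, spec)
        mm = bootstrap_memberships(g, spec, n_boot=1, seed=1, resample=False)
        for gene, cid in ref.membership.items():
            row = mm.rows.loc[gene]
            assert row[cid] == 1.0 and row.sum() == 1.0

    def test_clique_interiors_are_stable(self):
        g = nx.Graph()
        left = [f"L{i}" for i in range(8)]
        right = [f"R{i}" for i in range(8)]
        for group in (left, right):
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    g.add_edge(a, b)
        g.add_edge("L0", "R0")
        # infomap: modularity-based algorithms can fragment a clique once the
        # edge resampling thins it below ~2/3 density
        mm = bootstrap_memberships(g, AlgorithmSpec("infomap", seed=2), n_boot=100, seed=2)
        interior = [v for v in g.nodes if v not in ("L0", "R0")]
        assert (mm.rows.loc[interior].max(axis=1) >= 0.95).all()

    def test_rows_sum_to_one(self):
        net, _ = planted_partition_graph(30, 2, 0.5, 0.05, seed=6)
        mm = bootstrap_memberships(net, AlgorithmSpec("infomap", seed=3), n_boot=20, seed=3)
        assert np.allclose(mm.rows.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_n_boot(self, two_cliques):
        g, _, _ = two_cliques
        with pytest.raises(ValueError):
            bootstrap_memberships(g, AlgorithmSpec("walktrap"), n_boot=0)

    def test_membership_concentrates_as_blocks_separate(self):
        """Max membership entry grows as between-block density drops."""
        maxes = []
        for p_out in (0.15, 0.01):
            net, truth = planted_partition_graph(40, 2, 0.5, p_out, seed=8)
            mm = bootstrap_memberships(net, AlgorithmSpec("walktrap", seed=8), n_boot=30, seed=8)
            maxes.append(mm.rows.max(axis=1).mean())
        assert maxes[1] > maxes[0]


class TestConsensusPartition:
    def test_identical_inputs_returned(self):
        p = Partition({"A": 1, "B": 1, "C": 2})
        assert consensus_partition([p, p, p]).membership == p.membership

    def test_majority_rule_on_disputed_node(self):
        a = Partition({"A": 1, "B": 1, "C": 2, "D": 1})
        b = Partition({"A": 1, "B": 1, "C": 2, "D": 1})
        c = Partition({"A": 1, "B": 1, "C": 2, "D": 2})
        cons = consensus_partition([a, b, c])
        assert cons.membership["D"] == cons.membership["A"]

    def test_planted_blocks_consensus(self):
        net, truth = planted_partition_graph(60, 3, 0.5, 0.01, seed=2)
        parts = [detect_communities(net, AlgorithmSpec(a, seed=3))
                 for a in ("walktrap", "spinglass", "infomap")]
        cons = consensus_partition(parts)
        assert adjusted_agreement(cons, truth.partition) >= 0.9

    def test_inconsistent_node_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition([Partition({"A": 1}), Partition({"B": 1})])
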