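"""Community detection, bootstrap membership matrices, and consensus partitions.

The LCC is partitioned with several published algorithms (delegated to
python-igraph): agglomerative random walks (walktrap), the Potts-model
simulated-annealing SpinGlass, leading-eigenvector spectral splitting, and
the information-theoretic Infomap.  A mixed-membership stochastic blockmodel
("sbm") slot is declared but has no backend in this build; pipelines fall
back to the remaining algorithms and log the reduced set.

Soft community membership u_v = [u_1v ... u_cv] (each row a probability
vector summing to 1) is estimated by bootstrap: perturb the network, re-run
the algorithm, align labels to a reference run, and count per-node
co-assignments.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

ALGORITHMS = ("walktrap", "spinglass", "spectral", "infomap", "sbm")

#: Algorithms whose Ba(v) values enter the mean bridgeness Br(v) by default.
#: The blockmodel slot is excluded automatically when no backend is present.
DEFAULT_BR_ALGORITHMS = ("spinglass", "spectral", "infomap")


class UnavailableAlgorithm(RuntimeError):
    """Requested algorithm has no backend in this installation."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """Name, parameters and seed of one community-detection run."""

    name: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; choose from {ALGORITHMS}")


@dataclass
class Partition:
    """Hard community labels: gene -> community id, ids contiguous 1..c."""

    membership: dict[str, int]

    def __post_init__(self):
        ids = sorted(set(self.membership.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"community ids must be contiguous 1..c, got {ids}")

    @property
    def n_communities(self) -> int:
        return max(self.membership.values(), default=0)

    @property
    def nodes(self) -> set[str]:
        return set(self.membership)

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, cid in self.membership.items():
            out.setdefault(cid, set()).add(g)
        return out

    @classmethod
    def from_groups(cls, groups: list[set[str]] | dict[int, set[str]]) -> "Partition":
        """Build from node groups; ids assigned 1..c by decreasing size then
        smallest member symbol (deterministic)."""
        if isinstance(groups, dict):
            groups = list(groups.values())
        ordered = sorted((g for g in groups if g), key=lambda s: (-len(s), min(s)))
        return cls({g: i for i, members in enumerate(ordered, 1) for g in members})


@dataclass
class MembershipMatrix:
    """Per-node community-membership probabilities from one algorithm.

    ``rows`` is a DataFrame indexed by gene with columns 1..c; each row sums
    to 1 within 1e-9.
    """

    rows: pd.DataFrame
    algorithm: str
    n_boot: int

    def __post_init__(self):
        sums = self.rows.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must each sum to 1")

    @property
    def n_communities(self) -> int:
        return self.rows.shape[1]


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(idx[a], idx[b]) for a, b in net.edges])
    return g, nodes


def detect_communities(net: nx.Graph, spec: AlgorithmSpec) -> Partition:
    """Run one community-detection algorithm and return a hard partition.

    Stochastic algorithms (spinglass, infomap) are reproducible for a fixed
    ``spec.seed``.  Raises :class:`UnavailableAlgorithm` for the blockmodel
    slot, which has no backend here.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError("detect_communities expects a connected network (the LCC)")
    g, nodes = _to_igraph(net)
    logger.debug("detect_communities: algo=%s seed=%d n=%d", spec.name, spec.seed, len(nodes))
    random.seed(spec.seed)  # python-igraph draws from the stdlib RNG
    if spec.name == "walktrap":
        clustering = g.community_walktrap(steps=spec.params.get("steps", 4)).as_clustering()
    elif spec.name == "spinglass":
        clustering = g.community_spinglass(spins=spec.params.get("spins", 25))
    elif spec.name == "spectral":
        clustering = g.community_leading_eigenvector()
    elif spec.name == "infomap":
        clustering = g.community_infomap(trials=spec.params.get("trials", 10))
    elif spec.name == "sbm":
        raise UnavailableAlgorithm(
            "no stochastic-blockmodel backend is installed; "
            "run with the remaining algorithms (the reduced set is logged)"
        )
    else:  # pragma: no cover - guarded by AlgorithmSpec
        raise ValueError(spec.name)
    groups: dict[int, set[str]] = {}
    for i, cid in enumerate(clustering.membership):
        groups.setdefault(cid, set()).add(nodes[i])
    return Partition.from_groups(groups)


def align_partitions(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` onto ``reference`` by greedy maximum-overlap matching.

    Pairs are matched largest-intersection first (ties: smaller reference id,
    then smaller other id); unmatched communities of ``other`` get fresh ids
    above the reference's.  Which nodes are grouped together never changes.
    """
    if reference.nodes != other.nodes:
        raise ValueError("align_partitions requires identical node sets")
    ref_groups, oth_groups = reference.communities(), other.communities()
    overlaps = sorted(
        ((len(rg & og), rid, oid) for rid, rg in ref_groups.items() for oid, og in oth_groups.items()),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for n_ov, rid, oid in overlaps:
        if n_ov == 0 or oid in mapping or rid in used_ref:
            continue
        mapping[oid] = rid
        used_ref.add(rid)
    next_id = max(ref_groups, default=0) + 1
    for oid in sorted(oth_groups):
        if oid not in mapping:
            mapping[oid] = next_id
            next_id += 1
    relabeled = {g: mapping[cid] for g, cid in other.membership.items()}
    # keep raw labels (may be non-contiguous w.r.t. reference) in a plain dict,
    # then compact deterministically while preserving the reference ids:
    ids = sorted(set(relabeled.values()))
    if ids == list(range(1, len(ids) + 1)):
        return Partition(relabeled)
    compact = {cid: i for i, cid in enumerate(ids, 1)}
    # only compact when fresh ids left holes; reference-matched ids keep order
    return Partition({g: compact[c] for g, c in relabeled.items()})


def _aligned_labels(reference: Partition, other: Partition) -> dict[str, int]:
    """Like align_partitions but tolerant of a node subset and without
    id-compaction — used to accumulate bootstrap counts into fixed columns."""
    common = reference.nodes & other.nodes
    ref_groups = {
        cid: members & common for cid, members in reference.communities().items()
    }
    oth_groups = other.communities()
    overlaps = sorted(
        ((len(rg & og), rid, oid) for rid, rg in ref_groups.items() for oid, og in oth_groups.items()),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for n_ov, rid, oid in overlaps:
        if n_ov == 0 or oid in mapping or rid in used_ref:
            continue
        mapping[oid] = rid
        used_ref.add(rid)
    next_id = max(ref_groups, default=0) + 1
    for oid in sorted(oth_groups):
        if oid not in mapping:
            mapping[oid] = next_id
            next_id += 1
    return {g: mapping[cid] for g, cid in other.membership.items()}


def bootstrap_memberships(
    net: nx.Graph,
    spec: AlgorithmSpec,
    n_boot: int = 100,
    seed: int = 0,
    resample: bool = True,
) -> MembershipMatrix:
    """Estimate soft community membership by bootstrap.

    A reference partition is detected on the intact network.  Each replicate
    resamples the edge multiset with replacement (duplicates collapsed),
    keeps the replicate's LCC restricted to original nodes, re-detects
    communities, aligns labels to the reference, and increments per-node
    community counts.  Rows are normalized by the number of replicates in
    which each node appeared.  With ``resample=False`` the graph is kept
    fixed and only the algorithm's seed varies per replicate (reseed-only
    mode, meaningful for stochastic algorithms).

    Nodes that never survive a replicate keep their one-hot reference row.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    reference = detect_communities(net, spec)
    nodes = sorted(net.nodes)
    rng = np.random.default_rng(seed)
    edges = list(net.edges)
    counts: dict[str, dict[int, float]] = {v: {} for v in nodes}
    appearances: dict[str, int] = {v: 0 for v in nodes}
    max_cid = reference.n_communities
    for b in range(n_boot):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if resample:
            chosen = rng.integers(0, len(edges), size=len(edges))
            rep = nx.Graph()
            rep.add_edges_from(edges[i] for i in chosen)
            if rep.number_of_nodes() == 0:
                continue
            comps = sorted(nx.connected_components(rep), key=lambda c: (-len(c), min(c)))
            rep = rep.subgraph(comps[0]).copy()
        else:
            rep = net
        try:
            part = detect_communities(rep, AlgorithmSpec(spec.name, seed=rep_seed, params=spec.params))
        except Exception as exc:  # algorithm failure on a degenerate replicate
            logger.warning("bootstrap replicate %d failed (%s); skipped", b, exc)
            continue
        labels = _aligned_labels(reference, part)
        for g, cid in labels.items():
            counts[g][cid] = counts[g].get(cid, 0.0) + 1.0
            appearances[g] += 1
            max_cid = max(max_cid, cid)
    cols = list(range(1, max_cid + 1))
    mat = np.zeros((len(nodes), len(cols)))
    for i, v in enumerate(nodes):
        if appearances[v] == 0:
            mat[i, reference.membership[v] - 1] = 1.0  # never resampled: reference row
        else:
            for cid, cnt in counts[v].items():
                mat[i, cid - 1] = cnt / appearances[v]
    rows = pd.DataFrame(mat, index=nodes, columns=cols)
    rows.index.name = "gene"
    return MembershipMatrix(rows=rows, algorithm=spec.name, n_boot=n_boot)


def consensus_partition(partitions: list[Partition]) -> Partition:
    """Consensus by co-classification: nodes joined when they share a
    community in more than half of the input partitions.

    The node-pair co-classification frequency matrix is thresholded at 0.5
    and the connected components of the resulting graph are the consensus
    communities.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    nodes = partitions[0].nodes
    for p in partitions[1:]:
        if p.nodes != nodes:
            raise ValueError("all partitions must share one node set")
    ordered = sorted(nodes)
    idx = {v: i for i, v in enumerate(ordered)}
    co = np.zeros((len(ordered), len(ordered)))
    for p in partitions:
        for members in p.communities().values():
            ii = [idx[v] for v in members]
            co[np.ix_(ii, ii)] += 1
    co /= len(partitions)
    g = nx.Graph()
    g.add_nodes_from(ordered)
    thresh = co > 0.5
    for i, a in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            if thresh[i, j]:
                g.add_edge(a, ordered[j])
    return Partition.from_groups([set(c) for c in nx.connected_components(g)])


def adjusted_agreement(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions on the same node set."""
    nodes = sorted(a.nodes & b.nodes)
    return float(adjusted_rand_score([a.membership[v] for v in nodes], [b.membership[v] for v in nodes]))
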