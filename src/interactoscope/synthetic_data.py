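"""Seeded generators for every input the pipeline consumes.

Real bait interactomes come from affinity-purification mass spectrometry
runs filtered against curated interaction databases; none of that is
reproducible offline.  These generators instead emit data with the same
statistical structure the analysis assumes — sparse modular networks of a
few hundred nodes, planted bridge nodes wired across communities,
annotation terms concentrated in single communities, and disease gene sets
with controlled topological overlap — together with the ground truth needed
to score recovery.  All generators are deterministic in their seed.

Synthetic gene symbols are ``G000001``-style; bridge nodes are ``BRG01``-
style so planted structure is visible in fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .community import Partition
from .enrichment import AnnotationSet

_GENE_FMT = "G{:06d}"
_BRIDGE_FMT = "BRG{:02d}"
_TERM_FMT = "T{:04d}"


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    partition: Partition
    bridges: set[str] = field(default_factory=set)
    enriched_pairs: list[tuple[int, str]] = field(default_factory=list)
    disease_pairs: list[tuple[str, str, int]] = field(default_factory=list)


def planted_partition_graph(
    n_nodes: int = 60,
    n_comms: int = 3,
    p_in: float = 0.5,
    p_out: float = 0.01,
    seed: int = 0,
) -> tuple[nx.Graph, PlantedTruth]:
    """Planted-partition random graph reduced to its LCC.

    Nodes split into ``n_comms`` near-equal blocks; within-block pairs are
    edges with probability ``p_in``, between-block pairs with ``p_out``.
    The returned graph is the largest connected component and the truth
    partition is restricted to it (block ids re-ranked 1..c by size).
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_nodes < n_comms:
        raise ValueError("n_nodes must be >= n_comms")
    rng = np.random.default_rng(seed)
    nodes = [_GENE_FMT.format(i + 1) for i in range(n_nodes)]
    block = {v: (i % n_comms) + 1 for i, v in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        p = p_in if block[a] == block[b] else p_out
        if rng.random() < p:
            g.add_edge(a, b)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    lcc = g.subgraph(comps[0]).copy()
    groups: dict[int, set[str]] = {}
    for v in lcc:
        groups.setdefault(block[v], set()).add(v)
    truth = PlantedTruth(partition=Partition.from_groups(groups))
    return lcc, truth


def add_bridge_nodes(
    net: nx.Graph,
    truth: PlantedTruth,
    n_bridges: int = 3,
    degree_per_comm: int = 3,
    n_comms_per_bridge: int = 2,
    seed: int = 0,
) -> tuple[nx.Graph, PlantedTruth]:
    """Plant bridge nodes wired evenly into multiple communities.

    Each new node connects to ``degree_per_comm`` uniformly chosen members
    of each of ``n_comms_per_bridge`` (>= 2) communities, so that its true
    membership is split across them.  Bridges are recorded in
    ``truth.bridges``; in the hard truth partition each bridge is assigned
    to the first community it was wired into (a bridge has no single true
    community, so recovery tests should score the non-bridge nodes).
    """
    if n_bridges < 1 or degree_per_comm < 1 or n_comms_per_bridge < 2:
        raise ValueError("need n_bridges >= 1, degree_per_comm >= 1, n_comms_per_bridge >= 2")
    groups = truth.partition.communities()
    if n_comms_per_bridge > len(groups):
        raise ValueError("more communities requested per bridge than exist")
    if any(degree_per_comm > len(m) for m in groups.values()):
        raise ValueError("degree_per_comm exceeds a community's size")
    rng = np.random.default_rng(seed)
    g = net.copy()
    membership = dict(truth.partition.membership)
    bridges = set(truth.bridges)
    comm_ids = sorted(groups)
    for bi in range(n_bridges):
        name = _BRIDGE_FMT.format(bi + 1)
        targets = [comm_ids[(bi + j) % len(comm_ids)] for j in range(n_comms_per_bridge)]
        g.add_node(name)
        for cid in targets:
            members = sorted(groups[cid])
            for idx in rng.choice(len(members), size=degree_per_comm, replace=False):
                g.add_edge(name, members[idx])
        membership[name] = targets[0]
        bridges.add(name)
    new_truth = PlantedTruth(
        partition=Partition.from_groups(
            {cid: {v for v, c in membership.items() if c == cid} for cid in comm_ids}
        ),
        bridges=bridges,
        enriched_pairs=list(truth.enriched_pairs),
        disease_pairs=list(truth.disease_pairs),
    )
    return g, new_truth


def planted_annotations(
    truth: PlantedTruth,
    background_size: int = 500,
    n_terms: int = 6,
    frac_in: float = 0.8,
    frac_out: float = 0.01,
    seed: int = 0,
) -> tuple[AnnotationSet, PlantedTruth]:
    """Annotation terms enriched in specific communities, plus decoys.

    The background is the network's genes padded with filler symbols up to
    ``background_size``.  The first ``min(n_terms, c)`` terms each target
    one community, annotating ``frac_in`` of its members and ``frac_out``
    of the remaining background; any further terms are decoys annotating a
    uniform ``frac_out`` of the whole background.  Enriched (community,
    term) pairs are recorded in the returned truth.
    """
    if not (0 <= frac_out < frac_in <= 1):
        raise ValueError("need 0 <= frac_out < frac_in <= 1")
    groups = truth.partition.communities()
    if not groups:
        raise ValueError("truth partition has no communities")
    net_genes = sorted(truth.partition.nodes)
    fillers = [_GENE_FMT.format(i + 1) for i in range(900000, 900000 + max(0, background_size - len(net_genes)))]
    background = sorted(set(net_genes) | set(fillers))
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    enriched_pairs: list[tuple[int, str]] = []
    comm_ids = sorted(groups)
    for t in range(n_terms):
        term_id = _TERM_FMT.format(t + 1)
        if t < len(comm_ids):
            cid = comm_ids[t]
            members = sorted(groups[cid])
            n_in = max(1, round(frac_in * len(members)))
            inside = {members[i] for i in rng.choice(len(members), size=n_in, replace=False)}
            rest = sorted(set(background) - set(members))
            n_out = round(frac_out * len(rest))
            outside = {rest[i] for i in rng.choice(len(rest), size=n_out, replace=False)} if n_out else set()
            terms[term_id] = (f"planted in community {cid}", frozenset(inside | outside))
            enriched_pairs.append((cid, term_id))
        else:
            n_out = max(1, round(frac_out * len(background)))
            chosen = {background[i] for i in rng.choice(len(background), size=n_out, replace=False)}
            terms[term_id] = ("decoy", frozenset(chosen))
    new_truth = PlantedTruth(
        partition=truth.partition, bridges=set(truth.bridges),
        enriched_pairs=enriched_pairs, disease_pairs=list(truth.disease_pairs),
    )
    return AnnotationSet(terms=terms, background=frozenset(background)), new_truth


def planted_disease_pair(
    net: nx.Graph,
    truth: PlantedTruth,
    mode: str = "separated",
    size_a: int = 10,
    size_b: int = 10,
    jaccard: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, set[str]], int]:
    """Two disease gene sets with a known expected S_AB sign.

    ``separated`` samples the two sets from two different planted
    communities (expected S_AB > 0); ``overlapping`` samples both from one
    community with a shared fraction controlled by ``jaccard``
    (|A∩B| / |A∪B|; expected S_AB < 0).  Returns ({disease: genes},
    expected sign).
    """
    groups = truth.partition.communities()
    comm_ids = sorted(groups, key=lambda c: -len(groups[c]))
    rng = np.random.default_rng(seed)
    if mode == "separated":
        if len(comm_ids) < 2:
            raise ValueError("separated mode needs >= 2 communities")
        ca = sorted(groups[comm_ids[0]] - truth.bridges)
        cb = sorted(groups[comm_ids[1]] - truth.bridges)
        if size_a > len(ca) or size_b > len(cb):
            raise ValueError("requested sizes exceed community sizes")
        a = {ca[i] for i in rng.choice(len(ca), size=size_a, replace=False)}
        b = {cb[i] for i in rng.choice(len(cb), size=size_b, replace=False)}
        sign = +1
    elif mode == "overlapping":
        if not (0 < jaccard <= 1):
            raise ValueError("jaccard must be in (0, 1]")
        pool = sorted(groups[comm_ids[0]] - truth.bridges)
        n_shared = round(jaccard * (size_a + size_b) / (1 + jaccard))
        n_shared = min(n_shared, size_a, size_b)
        n_total = size_a + size_b - n_shared
        if n_total > len(pool):
            raise ValueError("community too small for the requested sizes")
        chosen = [pool[i] for i in rng.choice(len(pool), size=n_total, replace=False)]
        shared = set(chosen[:n_shared])
        a = shared | set(chosen[n_shared:n_shared + (size_a - n_shared)])
        b = shared | set(chosen[n_shared + (size_a - n_shared):])
        sign = -1
    else:
        raise ValueError("mode must be 'separated' or 'overlapping'")
    return {"DISEASE_A": a, "DISEASE_B": b}, sign


def synthetic_interactome_pair(
    genome_size: int = 24402,
    n_a: int = 373,
    n_b: int = 351,
    n_shared: int = 39,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Two interactor lists with an exact planted overlap.

    Defaults mirror a two-context bait comparison: lists of 373 and 351
    genes sharing exactly 39, against a 24,402-gene genome.
    """
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared exceeds a list size")
    if n_a + n_b - n_shared > genome_size:
        raise ValueError("lists cannot fit in the genome without extra overlap")
    rng = np.random.default_rng(seed)
    picks = rng.choice(genome_size, size=n_a + n_b - n_shared, replace=False)
    genes = [_GENE_FMT.format(i + 1) for i in picks]
    shared = genes[:n_shared]
    list_a = shared + genes[n_shared:n_shared + (n_a - n_shared)]
    list_b = shared + genes[n_shared + (n_a - n_shared):]
    return sorted(list_a), sorted(list_b)
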