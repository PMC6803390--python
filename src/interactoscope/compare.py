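"""Cross-interactome comparison: shared genes and community overlaps.

Two interactor lists obtained against the same bait in different biological
contexts (e.g., a tumor cell line versus synaptosomes) are compared by (a)
the hypergeometric probability of their gene overlap against a genome-sized
background, and (b) a community-by-community overlap p-value matrix that
identifies corresponding complexes across the two networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import Partition
from .enrichment import hypergeom_tail
from .graph_core import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    overlap: int
    genome_size: int
    p: float
    shared_genes: frozenset[str]


def list_overlap_test(list_a, list_b, genome_size: int) -> OverlapResult:
    """Hypergeometric test of the overlap between two gene lists.

    p = P(X >= |A ∩ B|) drawing |B| genes from a genome of ``genome_size``
    containing |A| marked genes; the test is symmetric in A and B.
    """
    a = {normalize_symbol(g) for g in list_a}
    b = {normalize_symbol(g) for g in list_b}
    if genome_size < len(a | b):
        raise ValueError("genome_size smaller than the union of the two lists")
    shared = a & b
    p = hypergeom_tail(k=len(shared), n=len(b), M=len(a), N=genome_size)
    return OverlapResult(len(a), len(b), len(shared), genome_size, p, frozenset(shared))


def cluster_pair_overlap(
    part_a: Partition,
    part_b: Partition,
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overlap p-value for every community pair across two
    partitions.

    For community i of A and community j of B the test statistic is the
    intersection size against a shared background, which defaults to the
    union of both partitions' node sets.  Empty (background-restricted)
    communities are skipped with a log entry.

    Returns a DataFrame indexed by A's community ids with B's ids as
    columns.
    """
    if background is None:
        background = part_a.nodes | part_b.nodes
    else:
        background = set(background)
        stray = (part_a.nodes | part_b.nodes) - background
        if stray:
            raise ValueError(f"background must cover both partitions; missing {sorted(stray)[:5]}")
    N = len(background)
    groups_a = {i: c & background for i, c in part_a.communities().items()}
    groups_b = {j: c & background for j, c in part_b.communities().items()}
    for label, groups in (("A", groups_a), ("B", groups_b)):
        for cid in [c for c, mem in groups.items() if not mem]:
            logger.info("partition %s community %d empty after background restriction; skipped", label, cid)
            del groups[cid]
    mat = pd.DataFrame(
        index=sorted(groups_a), columns=sorted(groups_b), dtype=float
    )
    for i, ca in groups_a.items():
        for j, cb in groups_b.items():
            k = len(ca & cb)
            mat.loc[i, j] = hypergeom_tail(k=k, n=len(cb), M=len(ca), N=N)
    mat.index.name = "community_a"
    mat.columns.name = "community_b"
    return mat
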