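"""Disease-module separation on an interactome network.

Two diseases A and B, each mapped to a gene set on the network, are compared
through nearest-neighbor shortest-path distances:

    d_AA  mean, over A's genes, of the hop distance to the nearest *other*
          gene of A (likewise d_BB);
    d_AB  symmetric mean: for every gene of A the distance to the nearest
          gene of B, and vice versa, averaged over all |A|+|B| values; a
          gene in both sets contributes 0.

The separation statistic is

    S_AB = d_AB - (d_AA + d_BB) / 2,

negative when the two disease modules topologically overlap, positive when
they occupy separated network neighborhoods; |S_AB| is bounded by the
network diameter.  Pairs with S_AB < -3 or S_AB > 0.1 are flagged "of
interest".  Significance comes from a fully randomized null — redrawing
same-sized gene sets uniformly from the network — via a z-score and a
two-sided normal p-value with Bonferroni stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Interest flags for S_AB, taken verbatim from the separation analysis.
INTEREST_LOW, INTEREST_HIGH = -3.0, 0.1


@dataclass
class DiseasePairResult:
    disease_a: str
    disease_b: str
    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    of_interest: bool


def _distances_from(net: nx.Graph, sources: set[str]) -> dict[str, dict[str, int]]:
    return {s: nx.single_source_shortest_path_length(net, s) for s in sources}


def intra_module_distance(net: nx.Graph, genes: set[str]) -> float:
    """Mean hop distance from each member gene to its nearest other member."""
    members = set(genes) & set(net.nodes)
    if len(members) < 2:
        raise ValueError("intra-module distance needs >= 2 genes on the network")
    total = 0.0
    for g in members:
        dist = nx.single_source_shortest_path_length(net, g)
        total += min(dist[o] for o in members if o != g)
    return total / len(members)


def cross_module_distance(net: nx.Graph, genes_a: set[str], genes_b: set[str]) -> float:
    """Symmetric nearest-neighbor mean distance between two gene sets.

    Genes present in both sets are at distance 0 from the other set.
    """
    a = set(genes_a) & set(net.nodes)
    b = set(genes_b) & set(net.nodes)
    if not a or not b:
        raise ValueError("both gene sets must map to >= 1 network node")
    vals = []
    for g in a:
        dist = nx.single_source_shortest_path_length(net, g)
        vals.append(0 if g in b else min(dist[o] for o in b))
    for g in b:
        dist = nx.single_source_shortest_path_length(net, g)
        vals.append(0 if g in a else min(dist[o] for o in a))
    return float(np.mean(vals))


def separation_score(net: nx.Graph, genes_a: set[str], genes_b: set[str]) -> float:
    """S_AB = d_AB - (d_AA + d_BB)/2."""
    d_aa = intra_module_distance(net, genes_a)
    d_bb = intra_module_distance(net, genes_b)
    d_ab = cross_module_distance(net, genes_a, genes_b)
    return d_ab - (d_aa + d_bb) / 2.0


def separation_null(
    net: nx.Graph,
    size_a: int,
    size_b: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Null distribution of S_AB for two random gene sets of the given sizes.

    Draws are uniform without replacement from the network's nodes,
    independently for the two diseases in every iteration.  Returns
    (sample mean, sample sd, the sample itself).
    """
    nodes = np.array(sorted(net.nodes))
    if size_a < 2 or size_b < 2:
        raise ValueError("null sizes must be >= 2")
    if max(size_a, size_b) > len(nodes):
        raise ValueError("requested size exceeds network node count")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    sample = np.empty(n_iter)
    for i in range(n_iter):
        a = set(nodes[rng.choice(len(nodes), size=size_a, replace=False)])
        b = set(nodes[rng.choice(len(nodes), size=size_b, replace=False)])
        sample[i] = separation_score(net, a, b)
    return float(sample.mean()), float(sample.std(ddof=1)), sample


def disease_pair_analysis(
    net: nx.Graph,
    gda: dict[str, set[str]],
    n_iter: int = 1000,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> "pd.DataFrame":
    """S_AB, null z-score and p-value for every disease pair.

    Diseases with fewer than 2 genes on the network are skipped with a
    warning.  Null distributions are cached per (|A|, |B|) size pair.  The
    final table carries Bonferroni-adjusted p-values over all pairs tested
    in this call and the S_AB interest flag.
    """
    import pandas as pd

    diam = nx.diameter(net)
    mapped = {}
    for d, genes in gda.items():
        on_net = set(genes) & set(net.nodes)
        if len(on_net) < 2:
            logger.warning("disease %s: only %d gene(s) on the network; skipped", d, len(on_net))
            continue
        if len(on_net) < len(genes):
            logger.info("disease %s: %d of %d genes mapped to the LCC", d, len(on_net), len(genes))
        mapped[d] = on_net
    names = sorted(mapped)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple[int, int], tuple[float, float]] = {}
    rows = []
    for a, b in pairs:
        ga, gb = mapped[a], mapped[b]
        d_aa = intra_module_distance(net, ga)
        d_bb = intra_module_distance(net, gb)
        d_ab = cross_module_distance(net, ga, gb)
        s_ab = d_ab - (d_aa + d_bb) / 2.0
        assert abs(s_ab) <= diam, "S_AB must be bounded by the network diameter"
        key = tuple(sorted((len(ga), len(gb))))
        if key not in null_cache:
            mu, sd, _ = separation_null(net, key[0], key[1], n_iter=n_iter,
                                        seed=int(rng.integers(0, 2**31 - 1)))
            null_cache[key] = (mu, sd)
        mu, sd = null_cache[key]
        z = (s_ab - mu) / sd
        p = 2.0 * float(norm.sf(abs(z)))
        rows.append(DiseasePairResult(
            a, b, d_aa, d_bb, d_ab, s_ab, mu, sd, z, min(1.0, p),
            of_interest=(s_ab < INTEREST_LOW or s_ab > INTEREST_HIGH),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
        df["stars"] = [sum(pb <= t for t in (0.05, 0.01, 0.001)) for pb in df["p_bonferroni"]]
    return df
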