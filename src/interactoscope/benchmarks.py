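"""Parameter-recovery experiments on planted synthetic data.

Each experiment generates data with known ground truth, runs the relevant
pipeline stage, and scores recovery.  They double as calibration evidence:
the generator defaults (60-node 3-block graphs at p_in = 0.5, p_out = 0.01,
3 bridges wired into 2 communities each, terms covering 80% of one
community versus 1% of the background) are the study conditions under which
the method is expected to work; the experiments measure whether it does.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from . import synthetic_data
from .bridgeness import influence_table
from .community import AlgorithmSpec, adjusted_agreement, bootstrap_memberships, detect_communities
from .disease_topology import separation_score
from .enrichment import cluster_term_enrichment
from .graph_core import semilocal_centrality


def clustering_agreement_experiment(
    seeds: list[int],
    algorithms: tuple[str, ...] = ("walktrap", "infomap"),
    n_nodes: int = 60,
    n_comms: int = 3,
    p_in: float = 0.5,
    p_out: float = 0.01,
) -> dict[str, list[float]]:
    """Adjusted Rand agreement of each algorithm with planted block labels."""
    out: dict[str, list[float]] = {a: [] for a in algorithms}
    for seed in seeds:
        net, truth = synthetic_data.planted_partition_graph(n_nodes, n_comms, p_in, p_out, seed=seed)
        for algo in algorithms:
            part = detect_communities(net, AlgorithmSpec(algo, seed=seed))
            out[algo].append(adjusted_agreement(part, truth.partition))
    return out


def bridge_recovery_experiment(
    seeds: list[int],
    algorithms: tuple[str, ...] = ("spinglass", "spectral", "infomap"),
    n_boot: int = 30,
    n_bridges: int = 3,
    degree_per_comm: int = 3,
) -> list[float]:
    """Per-seed AUC of mean bridgeness Br separating planted bridges from
    community-interior nodes."""
    aucs = []
    for seed in seeds:
        net, truth = synthetic_data.planted_partition_graph(seed=seed)
        net, truth = synthetic_data.add_bridge_nodes(
            net, truth, n_bridges=n_bridges, degree_per_comm=degree_per_comm, seed=seed)
        memberships = {
            a: bootstrap_memberships(net, AlgorithmSpec(a, seed=seed), n_boot=n_boot, seed=seed)
            for a in algorithms
        }
        cl = {g: v[1] for g, v in semilocal_centrality(net).items()}
        table = influence_table(cl, memberships)
        labels = [1 if g in truth.bridges else 0 for g in table.index]
        aucs.append(float(roc_auc_score(labels, table["br"])))
    return aucs


def enrichment_recovery_experiment(
    seeds: list[int],
    background_size: int = 500,
    n_terms: int = 6,
    frac_in: float = 0.8,
    frac_out: float = 0.01,
) -> tuple[float, float]:
    """(fraction of planted terms ranked 1 in their community,
    fraction of decoy tests Bonferroni-significant at 0.05)."""
    rank1 = rank1_total = 0
    decoy_sig = decoy_total = 0
    for seed in seeds:
        _, truth = synthetic_data.planted_partition_graph(seed=seed)
        ann, truth = synthetic_data.planted_annotations(
            truth, background_size=background_size, n_terms=n_terms,
            frac_in=frac_in, frac_out=frac_out, seed=seed)
        res = cluster_term_enrichment(truth.partition, ann)
        enriched = dict(truth.enriched_pairs)  # cid -> term
        enriched_terms = set(enriched.values())
        for cid, term in truth.enriched_pairs:
            sub = res[res.cluster == cid]
            rank1_total += 1
            if not sub.empty and sub.set_index("term")["p"].idxmin() == term:
                rank1 += 1
        decoys = res[~res.term.isin(enriched_terms)]
        n_decoy_terms = n_terms - len(truth.enriched_pairs)
        decoy_total += n_decoy_terms * truth.partition.n_communities
        decoy_sig += int((decoys["p_bonferroni"] <= 0.05).sum())
    return rank1 / rank1_total, (decoy_sig / decoy_total if decoy_total else 0.0)


def disease_sign_recovery_experiment(
    seeds: list[int],
    mode: str,
    size_a: int = 10,
    size_b: int = 10,
    jaccard: float = 0.5,
) -> float:
    """Fraction of seeds where S_AB carries the planted sign."""
    correct = 0
    for seed in seeds:
        net, truth = synthetic_data.planted_partition_graph(seed=seed)
        gda, sign = synthetic_data.planted_disease_pair(
            net, truth, mode=mode, size_a=size_a, size_b=size_b, jaccard=jaccard, seed=seed)
        s = separation_score(net, gda["DISEASE_A"], gda["DISEASE_B"])
        if np.sign(s) == sign:
            correct += 1
    return correct / len(seeds)
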