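"""Hypergeometric over-representation analysis with a permutation strength test.

For a gene list of size n drawn against a background of N genes, M of which
carry an annotation term, the enrichment p-value is the upper hypergeometric
tail

    p = P(X >= k) = 1 - sum_{i<k} C(M,i) C(N-M, n-i) / C(N,n),

evaluated in log space.  Per-cluster enrichment tests every (cluster, term)
pair; the Bonferroni family is all pairs tested in one invocation, with
significance stars at 0.05 / 0.01 / 0.001.  The strength-of-significance
test shuffles the annotation's gene labels over the background and reports
the percentage of permuted p-values at or below the observed one; strengths
below 1% are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .community import Partition

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Term -> (description, gene set) mappings over a declared background."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self):
        self.background = frozenset(self.background)
        clean = {}
        for term, (desc, genes) in self.terms.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(f"term {term}: genes not in background: {sorted(stray)[:5]}")
            clean[term] = (desc, genes)
        self.terms = clean

    @property
    def n_background(self) -> int:
        return len(self.background)


def hypergeom_tail(k: int, n: int, M: int, N: int) -> float:
    """Upper-tail P(X >= k) for k annotated genes in a list of n, with M of
    N background genes annotated.  k = 0 returns exactly 1."""
    if not (0 <= k <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, n={n}, M={M}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(hypergeom.sf(k - 1, N, M, n))


def cluster_term_enrichment(
    partition: Partition,
    annotations: AnnotationSet,
    clusters: list[int] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term in every cluster.

    Only (cluster, term) pairs with at least one annotated member (k >= 1)
    are reported.  Bonferroni adjustment uses all tested pairs in this call
    as the family; stars mark 0.05 / 0.01 / 0.001.
    """
    stray = partition.nodes - annotations.background
    if stray:
        raise ValueError(f"partition genes absent from background: {sorted(stray)[:10]}")
    N = annotations.n_background
    groups = partition.communities()
    if clusters is not None:
        groups = {cid: groups[cid] for cid in clusters}
    rows = []
    for cid in sorted(groups):
        members = groups[cid]
        n = len(members)
        for term in sorted(annotations.terms):
            desc, genes = annotations.terms[term]
            k = len(members & genes)
            if k == 0:
                continue
            M = len(genes)
            rows.append({
                "cluster": cid, "term": term, "description": desc,
                "k": k, "n": n, "M": M, "N": N,
                "p": hypergeom_tail(k, n, M, N),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    df["p_by"] = adjust_pvalues(df["p"].tolist(), method="benjamini_yekutieli")
    df["stars"] = [
        sum(pb <= a for a in (0.05, 0.01, 0.001)) for pb in df["p_bonferroni"]
    ]
    return df


def permutation_strength(
    observed_p: float,
    cluster_genes: set[str],
    term: str,
    annotations: AnnotationSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Strength of significance of one enrichment by label permutation.

    Each permutation shuffles the term's annotation labels uniformly over
    the background (equivalently, redraws the M annotated genes at random),
    recomputes the cluster's hypergeometric p, and the strength is
    100 * #{p_perm <= observed_p} / n_perm.  Ties count as <=.  Strengths
    below 1 (i.e., < 1%) are considered statistically significant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _, genes = annotations.terms[term]
    background = sorted(annotations.background)
    cluster = set(cluster_genes)
    n = len(cluster)
    M = len(genes)
    N = len(background)
    rng = np.random.default_rng(seed)
    bg = np.array(background)
    hits = 0
    for _ in range(n_perm):
        perm_genes = set(bg[rng.choice(N, size=M, replace=False)])
        k = len(cluster & perm_genes)
        if hypergeom_tail(k, n, M, N) <= observed_p:
            hits += 1
    return 100.0 * hits / n_perm


def adjust_pvalues(p_list, method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment; output keeps the input order, capped at 1.

    ``method`` is one of ``bonferroni``, ``benjamini_hochberg``,
    ``benjamini_yekutieli``.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh",
           "benjamini_yekutieli": "fdr_by"}[method]
    return multipletests(p, method=key)[1].tolist()
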