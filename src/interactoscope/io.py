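"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: TSV tables, GMT gene sets, and a documented
JSON network serialization (sorted node list + sorted edge pairs) chosen so
that repeated runs produce diff-stable output.  Floating-point TSV columns
are written at 6 significant digits; exact values live in JSON sidecars
where a stage needs them.
"""

from __future__ import annotations

import json
import logging

import networkx as nx
import pandas as pd

from .community import MembershipMatrix, Partition
from .enrichment import AnnotationSet
from .graph_core import FormatError, normalize_symbol

logger = logging.getLogger(__name__)


def parse_gmt(path) -> AnnotationSet:
    """Read a GMT file (term, description, member genes, tab-separated).

    Duplicate genes within a term are collapsed; a line with no genes is an
    error reported with its line number.  The background is the union of
    all annotated genes; callers with a wider universe should pass their
    own background via :func:`with_background`.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description and >= 1 gene")
            term, desc = cols[0], cols[1]
            genes = frozenset(normalize_symbol(g) for g in cols[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term} has no genes")
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term}")
            terms[term] = (desc, genes)
    if not terms:
        logger.warning("parse_gmt: %s is empty", path)
        return AnnotationSet(terms={}, background=frozenset())
    background = frozenset().union(*(g for _, g in terms.values()))
    return AnnotationSet(terms=terms, background=background)


def with_background(annotations: AnnotationSet, background: set[str]) -> AnnotationSet:
    """Rebind an annotation set to an explicit (wider) background."""
    return AnnotationSet(terms=dict(annotations.terms),
                         background=frozenset(background) | annotations.background)


def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc, genes = annotations.terms[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gda(path) -> dict[str, set[str]]:
    """Read gene-disease annotations from GMT or two-column TSV
    (``disease_id<TAB>gene``, one association per line)."""
    with open(path) as fh:
        first = fh.readline()
    if len(first.rstrip("\n").split("\t")) >= 3:
        ann = parse_gmt(path)
        return {term: set(genes) for term, (_, genes) in ann.terms.items()}
    gda: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'disease_id<TAB>gene'")
            gda.setdefault(cols[0], set()).add(normalize_symbol(cols[1]))
    return gda


def write_gda(gda: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(gda):
            for gene in sorted(gda[disease]):
                fh.write(f"{disease}\t{gene}\n")


def write_network_json(net: nx.Graph, path) -> None:
    """Serialize a network as {"nodes": sorted list, "edges": sorted pairs}."""
    payload = {
        "nodes": sorted(net.nodes),
        "edges": sorted([sorted(e)[0], sorted(e)[1]] for e in net.edges),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_network_json(path) -> nx.Graph:
    with open(path) as fh:
        payload = json.load(fh)
    g = nx.Graph()
    g.add_nodes_from(payload["nodes"])
    g.add_edges_from(tuple(e) for e in payload["edges"])
    return g


def write_edge_table(net: nx.Graph, path, interaction_type: str = "direct", source: str = "synthetic") -> None:
    """Write a network's edges as the canonical TSV edge table."""
    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        data = net.get_edge_data(a, b) or {}
        rows.append((a, b, data.get("interaction_type", interaction_type), data.get("source", source)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "interaction_type", "source"])
    df.to_csv(path, sep="\t", index=False)


def write_protein_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def write_partition(partition: Partition, path) -> None:
    df = pd.DataFrame(
        sorted(partition.membership.items()), columns=["gene", "community"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "community": int})
    if list(df.columns) != ["gene", "community"]:
        raise FormatError(f"{path}: expected columns gene, community")
    return Partition(dict(zip(df["gene"], df["community"])))


def write_membership(matrix: MembershipMatrix, path) -> None:
    out = matrix.rows.copy()
    out.columns = [f"u{c}" for c in out.columns]
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_membership(path, algorithm: str = "unknown", n_boot: int = 0) -> MembershipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.columns = [int(c.lstrip("u")) for c in df.columns]
    # renormalize away 6-sig-digit rounding
    df = df.div(df.sum(axis=1), axis=0)
    return MembershipMatrix(rows=df, algorithm=algorithm, n_boot=n_boot)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
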