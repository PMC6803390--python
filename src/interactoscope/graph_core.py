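"""Network construction and node-centrality measures for interactome analysis.

A bait interactome is modelled as the simple undirected graph induced by a
protein list over a filtered physical-interaction edge table.  All topology
statistics downstream (communities, bridgeness, disease separation) run on
the largest connected component (LCC) of that graph.

Gene identifiers are uppercased symbols; comparison is case-insensitive.
Distances are unweighted BFS hop counts throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for :func:`read_edge_table` meaning "no interaction-type filter".
ACCEPT_ALL = "accept-all"

#: Default allow-list for the "direct and physical" interaction filter.
#: MI:0407 = direct interaction, MI:0915 = physical association.  The looser
#: MI:0914 (association) is deliberately excluded.  Free-text labels are kept
#: for plain TSV tables that do not use MI ids.
DIRECT_PHYSICAL_TYPES = frozenset(
    {"MI:0407", "MI:0915", "direct interaction", "physical association", "direct"}
)


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and reject empty/whitespace tokens."""
    s = str(symbol).strip().upper()
    if not s or any(ch.isspace() for ch in s):
        raise ValueError(f"invalid gene symbol: {symbol!r}")
    return s


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected physical interaction between two gene symbols."""

    a: str
    b: str
    interaction_type: str
    source: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, canonically sorted."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


def read_protein_list(path) -> list[str]:
    """Read one gene symbol per line; ``#`` starts a comment; dedup, keep order."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                seen.setdefault(normalize_symbol(token), None)
    return list(seen)


def read_edge_table(path, allowed_types: Iterable[str] | str = ACCEPT_ALL) -> list[InteractionRecord]:
    """Read a TSV edge table and apply the interaction-type allow-list.

    The table must have columns ``gene_a``, ``gene_b``, ``interaction_type``
    and ``source`` (header row required).  Records whose type is not in
    ``allowed_types`` are dropped, as are self-loops; duplicate unordered
    pairs are collapsed keeping the first source seen.

    Parameters
    ----------
    path
        TSV file path.
    allowed_types
        Set of accepted interaction-type tokens, or the :data:`ACCEPT_ALL`
        sentinel to keep every type.

    Returns
    -------
    list of :class:`InteractionRecord`
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["gene_a", "gene_b", "interaction_type", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"edge table {path} missing columns: {missing}")
    accept_all = isinstance(allowed_types, str) and allowed_types == ACCEPT_ALL
    if not accept_all:
        allowed = set(allowed_types)
        if not allowed:
            raise ValueError("allowed_types must be non-empty or the accept-all sentinel")
    records: dict[tuple[str, str], InteractionRecord] = {}
    n_dup = n_self = 0
    for row in df.itertuples(index=False):
        itype = (row.interaction_type or "").strip()
        if not accept_all and itype not in allowed:
            continue
        a, b = normalize_symbol(row.gene_a), normalize_symbol(row.gene_b)
        if a == b:
            n_self += 1
            continue
        rec = InteractionRecord(a, b, itype, str(row.source) if pd.notna(row.source) else "")
        if rec.pair in records:
            n_dup += 1
        else:
            records[rec.pair] = rec
    if n_dup or n_self:
        logger.info("read_edge_table: dropped %d duplicate pairs, %d self-loops", n_dup, n_self)
    if not records:
        logger.warning("read_edge_table: no interactions retained from %s", path)
    return list(records.values())


def read_psimitab(path, allowed_types: Iterable[str] | str = ACCEPT_ALL) -> list[InteractionRecord]:
    """Read a PSI-MI TAB 2.5 file, mapping columns 1,2 (ids), 12 (type), 13 (source).

    Interactor ids like ``uniprotkb:P12345`` keep the part after the last
    colon; interaction types like ``psi-mi:"MI:0407"(direct interaction)``
    are reduced to the MI id.
    """

    def _strip_db(token: str) -> str:
        return token.rsplit(":", 1)[-1].strip('"')

    def _mi_id(token: str) -> str:
        # psi-mi:"MI:0407"(direct interaction) -> MI:0407
        if '"' in token:
            inner = token.split('"')
            if len(inner) >= 2:
                return inner[1]
        return token.strip()

    records: dict[tuple[str, str], InteractionRecord] = {}
    accept_all = isinstance(allowed_types, str) and allowed_types == ACCEPT_ALL
    allowed = None if accept_all else set(allowed_types)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 13:
                raise FormatError(f"{path}:{lineno}: PSI-MI TAB 2.5 needs >= 13 columns")
            itype = _mi_id(cols[11])
            if allowed is not None and itype not in allowed:
                continue
            a = normalize_symbol(_strip_db(cols[0]))
            b = normalize_symbol(_strip_db(cols[1]))
            if a == b:
                continue
            rec = InteractionRecord(a, b, itype, _mi_id(cols[12]))
            records.setdefault(rec.pair, rec)
    return list(records.values())


def build_induced_network(proteins: Iterable[str], interactions: Iterable[InteractionRecord]) -> nx.Graph:
    """Build the simple graph induced by ``proteins`` over ``interactions``.

    Nodes are every listed protein (isolated ones kept with degree 0);
    edges are the interactions whose both endpoints are listed.
    """
    nodes = [normalize_symbol(p) for p in proteins]
    if not nodes:
        raise ValueError("protein list is empty")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    for rec in interactions:
        if rec.a in node_set and rec.b in node_set and rec.a != rec.b:
            g.add_edge(rec.a, rec.b, interaction_type=rec.interaction_type, source=rec.source)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component; ties broken by the
    lexicographically smallest member symbol (deterministic)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    best = comps[0]
    return net.subgraph(best).copy()


def semilocal_centrality(net: nx.Graph) -> dict[str, tuple[float, float]]:
    """Semi-local centrality Cl(v) with unity-based normalization.

    N(w) counts the nodes at hop distance 1 or 2 from ``w`` (``w`` excluded);
    Q(u) = sum of N(w) over neighbours w of u; Cl(v) = sum of Q(u) over
    neighbours u of v.  Normalization is (Cl - min)/(max - min); when every
    node ties (max == min) all normalized values are set to 0.5 so that a
    fully symmetric graph sits on neither influence extreme.

    Returns
    -------
    dict mapping node -> (raw Cl, normalized Cl in [0, 1])
    """
    if net.number_of_nodes() < 2:
        raise ValueError("semi-local centrality needs >= 2 nodes (normalization undefined)")
    if not nx.is_connected(net):
        raise ValueError("run semilocal_centrality on a connected graph (take the LCC first)")
    n_two_hop: dict[str, int] = {}
    for w in net:
        reach = set(net[w])
        for u in list(reach):
            reach.update(net[u])
        reach.discard(w)
        n_two_hop[w] = len(reach)
    q = {u: sum(n_two_hop[w] for w in net[u]) for u in net}
    cl = {v: float(sum(q[u] for u in net[v])) for v in net}
    lo, hi = min(cl.values()), max(cl.values())
    if hi == lo:
        return {v: (cl[v], 0.5) for v in net}
    return {v: (cl[v], (cl[v] - lo) / (hi - lo)) for v in net}


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """All node-centrality measures on the LCC, one row per gene.

    Columns: degree, betweenness (unnormalized pair counts), closeness,
    clustering_coefficient, pagerank (damping 0.85, tol 1e-10),
    semilocal_raw, semilocal_norm, mean_shortest_path.
    """
    if not nx.is_connected(net):
        raise ValueError("centrality_table requires a connected network; take the LCC first")
    sl = semilocal_centrality(net)
    bet = nx.betweenness_centrality(net, normalized=False)
    clo = nx.closeness_centrality(net)
    cc = nx.clustering(net)
    pr = nx.pagerank(net, alpha=0.85, tol=1e-10, max_iter=1000)
    n = net.number_of_nodes()
    msp = {
        v: sum(d.values()) / (n - 1)
        for v, d in nx.shortest_path_length(net)
    }
    rows = {
        "degree": {v: net.degree(v) for v in net},
        "betweenness": bet,
        "closeness": clo,
        "clustering_coefficient": cc,
        "pagerank": pr,
        "semilocal_raw": {v: sl[v][0] for v in net},
        "semilocal_norm": {v: sl[v][1] for v in net},
        "mean_shortest_path": msp,
    }
    df = pd.DataFrame(rows).loc[sorted(net.nodes)]
    df.index.name = "gene"
    return df


def network_diameter(net: nx.Graph) -> int:
    """Hop-count diameter; defined only for connected graphs."""
    if not nx.is_connected(net):
        raise ValueError("diameter defined only for connected networks")
    return nx.diameter(net)
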