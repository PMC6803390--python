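"""End-to-end pipeline driver: build → cluster → bridge → enrich → separate.

A :class:`RunConfig` holds every input path, algorithm seed and iteration
count; all randomness flows from its seeds, so a rerun with the same config
reproduces every output file byte for byte.  The config itself is
serialized into the output directory alongside a log of versions and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, bridgeness, community, disease_topology, enrichment, graph_core, io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    proteins: str
    edges: str
    out_dir: str
    seed: int
    gmt: str | None = None
    gda: str | None = None
    allowed_types: list[str] | str = graph_core.ACCEPT_ALL
    algorithms: list[str] = field(default_factory=lambda: ["walktrap", "spinglass", "spectral", "infomap"])
    br_algorithms: list[str] = field(default_factory=lambda: list(community.DEFAULT_BR_ALGORITHMS))
    headline_algorithm: str = "spinglass"
    n_boot: int = 50
    n_perm: int = 1000
    n_iter: int = 1000
    take_lcc: bool = True
    resample: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must declare a seed before any compute runs")
        for a in self.algorithms:
            if a not in community.ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")
        if self.headline_algorithm not in self.algorithms:
            raise ValueError("headline_algorithm must be among algorithms")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write its outputs under ``config.out_dir``.

    Stages: network build (+LCC), centrality table, per-algorithm
    partitions and bootstrap memberships, influence table, per-cluster
    enrichment (when a GMT is given), disease separation (when GDA data are
    given).  Stage failures abort with the stage name and cause.

    Returns the output directory path.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    log_lines = [f"interactoscope {__version__}", f"seed {config.seed}"]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- build ---
    def _build():
        proteins = graph_core.read_protein_list(config.proteins)
        records = graph_core.read_edge_table(config.edges, config.allowed_types)
        net = graph_core.build_induced_network(proteins, records)
        if config.take_lcc:
            net = graph_core.largest_connected_component(net)
        return net

    net = stage("build", _build)
    io.write_network_json(net, out / "network.json")
    log_lines.append(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

    ct = stage("centrality", lambda: graph_core.centrality_table(net))
    io.write_tsv(ct.reset_index(), out / "centrality.tsv")

    # --- cluster ---
    partitions: dict[str, community.Partition] = {}
    memberships: dict[str, community.MembershipMatrix] = {}
    for i, name in enumerate(config.algorithms):
        spec = community.AlgorithmSpec(name, seed=config.seed + i)
        try:
            partitions[name] = stage(f"cluster:{name}", lambda s=spec: community.detect_communities(net, s))
        except RuntimeError as exc:
            if isinstance(exc.__cause__, community.UnavailableAlgorithm):
                log_lines.append(f"algorithm {name} unavailable; reduced set in use")
                logger.warning("algorithm %s unavailable; continuing without it", name)
                continue
            raise
        io.write_partition(partitions[name], out / f"partition_{name}.tsv")
        if name in config.br_algorithms:
            mm = stage(
                f"bootstrap:{name}",
                lambda s=spec: community.bootstrap_memberships(
                    net, s, n_boot=config.n_boot, seed=config.seed + 1000 + i,
                    resample=config.resample,
                ),
            )
            memberships[name] = mm
            io.write_membership(mm, out / f"membership_{name}.tsv")
    cons = stage("consensus", lambda: community.consensus_partition(list(partitions.values())))
    io.write_partition(cons, out / "partition_consensus.tsv")
    log_lines.append(f"algorithms run: {sorted(partitions)}")

    # --- bridge ---
    cl_norm = {g: ct.loc[g, "semilocal_norm"] for g in net.nodes}
    usable = {n: m for n, m in memberships.items() if m.n_communities >= 2}
    if usable:
        infl = stage("bridge", lambda: bridgeness.influence_table(cl_norm, usable))
        io.write_tsv(infl.reset_index(), out / "influence.tsv")
        log_lines.append(f"bridgeness algorithms: {sorted(usable)}")

    # --- enrich ---
    if config.gmt:
        headline = partitions[config.headline_algorithm]
        ann = io.parse_gmt(config.gmt)
        ann = io.with_background(ann, set(headline.nodes))
        enr = stage("enrich", lambda: enrichment.cluster_term_enrichment(headline, ann))
        if not enr.empty:
            strengths = []
            for row in enr.itertuples():
                if row.p <= 0.01:
                    strengths.append(enrichment.permutation_strength(
                        row.p, headline.communities()[row.cluster], row.term, ann,
                        n_perm=config.n_perm, seed=config.seed + 2000,
                    ))
                else:
                    strengths.append(float("nan"))
            enr["strength_pct"] = strengths
        io.write_tsv(enr, out / "enrichment.tsv")

    # --- separate ---
    if config.gda:
        gda = io.read_gda(config.gda)
        sep = stage("separate", lambda: disease_topology.disease_pair_analysis(
            net, gda, n_iter=config.n_iter, seed=config.seed + 3000))
        io.write_tsv(sep, out / "separation.tsv")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
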