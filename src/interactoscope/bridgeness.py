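"""Bridgeness scores and the influence-quadrant classification.

A node's bridgeness under one clustering algorithm,

    Ba(v) = 1 - sqrt( c/(c-1) * sum_j (u_jv - 1/c)^2 ),

measures how far its community-membership probability vector u_v sits from
the uniform vector: 0 for a node fully inside one community (one-hot row),
1 for a node shared equally across all c communities.  The square root is
part of the corrected bridgeness definition; it is the only reading under
which the uniform row scores exactly 1 with the c/(c-1) normalizer.  A
``sqrt=False`` compatibility switch evaluates the unrooted variant.

Br(v) is the arithmetic mean of Ba(v) over the configured algorithm set.
Plotting Br against normalized semi-local centrality Cl splits nodes into
four influence regions:

    R1 global bridge   Cl < 0.5, Br >= 0.5
    R2 mixed bridge    Cl >= 0.5, Br >= 0.5
    R3 local hub       Cl < 0.5, 0.1 <= Br < 0.5
    R4 local only      everything else (Br < 0.5 with high Cl, or Br < 0.1)

"Bridging proteins" are those in R1 or R2.  Boundaries are half-open so the
classification is total and disjoint on [0,1]^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("R1_global_bridge", "R2_mixed_bridge", "R3_local_hub", "R4_local_only")


def bridgeness_single(u_row: Sequence[float], c: int | None = None, sqrt: bool = True) -> float:
    """Bridgeness of one membership probability row.

    Parameters
    ----------
    u_row
        Probability vector over the c communities; must sum to 1.
    c
        Number of communities; defaults to ``len(u_row)``.  Must be >= 2.
    sqrt
        Apply the square root of the corrected definition (default).
    """
    u = np.asarray(u_row, dtype=float)
    if c is None:
        c = u.size
    if c < 2:
        raise ValueError("bridgeness undefined for a single community (c < 2)")
    if u.size != c:
        raise ValueError(f"row length {u.size} != c = {c}")
    if not math.isclose(float(u.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("membership row must sum to 1")
    ss = float(np.sum((u - 1.0 / c) ** 2))
    val = (c / (c - 1)) * ss
    ba = 1.0 - (math.sqrt(val) if sqrt else val)
    return min(1.0, max(0.0, ba))


def mean_bridgeness(ba_per_algorithm: Mapping[str, float]) -> float:
    """Arithmetic mean of per-algorithm bridgeness values."""
    if not ba_per_algorithm:
        raise ValueError("need at least one algorithm's bridgeness")
    return float(np.mean(list(ba_per_algorithm.values())))


def classify_region(cl_norm: float, br: float) -> str:
    """Map (normalized semi-local centrality, mean bridgeness) to a region."""
    if not (0.0 <= cl_norm <= 1.0 and 0.0 <= br <= 1.0):
        raise ValueError(f"(cl_norm, br) must lie in [0,1]^2, got ({cl_norm}, {br})")
    if br >= 0.5:
        return "R1_global_bridge" if cl_norm < 0.5 else "R2_mixed_bridge"
    if cl_norm >= 0.5:
        return "R4_local_only"
    return "R3_local_hub" if br >= 0.1 else "R4_local_only"


@dataclass
class InfluenceRecord:
    gene: str
    cl_norm: float
    ba_per_algorithm: dict[str, float]
    br: float
    region: str


def influence_table(
    cl_norm: Mapping[str, float],
    memberships: Mapping[str, "pd.DataFrame | object"],
    sqrt: bool = True,
) -> pd.DataFrame:
    """Per-node influence summary across algorithms.

    Parameters
    ----------
    cl_norm
        gene -> normalized semi-local centrality (from the full LCC).
    memberships
        algorithm name -> :class:`~interactoscope.community.MembershipMatrix`.
        Matrices with a single community carry no bridging signal and are
        skipped.

    Returns
    -------
    DataFrame indexed by gene with one ``ba_<algorithm>`` column per usable
    algorithm, plus ``cl_norm``, ``br`` and ``region``.
    """
    genes = sorted(cl_norm)
    data: dict[str, list[float]] = {}
    for name, mm in memberships.items():
        rows = mm.rows if hasattr(mm, "rows") else mm
        if rows.shape[1] < 2:
            continue
        data[f"ba_{name}"] = [
            bridgeness_single(rows.loc[g].to_numpy(), sqrt=sqrt) for g in genes
        ]
    if not data:
        raise ValueError("no membership matrix with >= 2 communities supplied")
    df = pd.DataFrame(data, index=genes)
    df.insert(0, "cl_norm", [cl_norm[g] for g in genes])
    df["br"] = df[[c for c in df.columns if c.startswith("ba_")]].mean(axis=1)
    df["region"] = [classify_region(r.cl_norm, r.br) for r in df.itertuples()]
    df.index.name = "gene"
    return df


def plot_influence_quadrants(table: pd.DataFrame, path=None):  # pragma: no cover
    """Optional Br-vs-Cl scatter with the four region boundaries marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = {"R1_global_bridge": "tab:red", "R2_mixed_bridge": "tab:orange",
              "R3_local_hub": "tab:blue", "R4_local_only": "0.6"}
    for region, sub in table.groupby("region"):
        ax.scatter(sub["cl_norm"], sub["br"], s=14, label=region, c=colors.get(region))
    ax.axhline(0.5, ls="--", c="k", lw=0.8)
    ax.axhline(0.1, ls=":", c="k", lw=0.8)
    ax.axvline(0.5, ls="--", c="k", lw=0.8)
    ax.set_xlabel("semi-local centrality Cl (normalized)")
    ax.set_ylabel("mean bridgeness Br")
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
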