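"""Betweenness backbones and the hub/bottleneck role taxonomy.

The backbone of an interaction network is the subgraph induced on the
top fraction of nodes ranked by betweenness centrality (default 20%):
these are the heavily used intersections through which most shortest
paths flow.  Independently, nodes in the top fraction by degree
(default 10%) are *hubs* and nodes in the top fraction by betweenness
(default 10%) are *bottlenecks*.  Crossing the two predicates gives
the role taxonomy:

    date-hub            hub and bottleneck  (connects modules)
    party-hub           hub, not bottleneck (acts inside a module)
    nonhub-bottleneck   bottleneck, not hub
    other               neither

All percentile selections are rank-based with tie extension: the k-th
ranked value becomes an inclusive threshold, so equal-valued nodes at
the boundary are all selected and the cutoff is auditable as a plain
"DC >= t" / "BC >= t" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "ThresholdConfig",
    "BackboneNetwork",
    "rank_threshold",
    "extract_backbone",
    "classify_roles",
    "summarize_backbone",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Top-fraction cutoffs for backbone extraction and role calls."""

    backbone_fraction: float = 0.20
    hub_fraction: float = 0.10
    bottleneck_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("backbone_fraction", "hub_fraction", "bottleneck_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class BackboneNetwork:
    """Induced subgraph on the top-betweenness nodes plus their records."""

    graph: nx.Graph
    records: pd.DataFrame  # centrality rows of the selected nodes
    bc_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.records["node"])


def rank_threshold(values: pd.Series, fraction: float) -> float:
    """Value of the ceil(fraction*n)-th ranked entry (descending).

    Selecting ``value >= threshold`` afterwards keeps the top
    ``fraction`` of entries, extended through ties at the boundary.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(values))
    if k == 0:
        raise ValueError("fraction selects zero nodes")
    return values.sort_values(ascending=False).iloc[k - 1]


def extract_backbone(
    graph: nx.Graph,
    records: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> BackboneNetwork:
    """Induce the backbone on the top-betweenness fraction of nodes.

    ``records`` must carry one centrality row per graph node.  The
    induced subgraph may be disconnected even if the input is not.
    """
    missing = set(map(str, graph.nodes)) - set(records["node"])
    if missing:
        raise ValueError(f"records missing for nodes: {sorted(missing)[:5]}")
    thr = rank_threshold(records["betweenness"], cfg.backbone_fraction)
    selected = records[records["betweenness"] >= thr].reset_index(drop=True)
    sub = graph.subgraph(selected["node"]).copy()
    return BackboneNetwork(graph=sub, records=selected, bc_threshold=thr)


def classify_roles(
    records: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
    dc_threshold: float | None = None,
    bc_threshold: float | None = None,
) -> pd.DataFrame:
    """Assign hub/bottleneck flags and the four-way role to every node.

    Hub and bottleneck thresholds are computed over *all* supplied
    records, so pass the full giant component, not just the backbone.
    When the full component is unavailable (e.g. a published backbone
    table), supply the known value cutoffs via ``dc_threshold`` /
    ``bc_threshold``; they override the fraction-derived ones.
    Returns the records with ``is_hub``, ``is_bottleneck`` and
    ``role`` columns appended.
    """
    if len(records) == 0:
        raise ValueError("no centrality records supplied")
    dc_thr = (
        dc_threshold
        if dc_threshold is not None
        else rank_threshold(records["degree"], cfg.hub_fraction)
    )
    bc_thr = (
        bc_threshold
        if bc_threshold is not None
        else rank_threshold(records["betweenness"], cfg.bottleneck_fraction)
    )
    out = records.copy()
    out["is_hub"] = out["degree"] >= dc_thr
    out["is_bottleneck"] = out["betweenness"] >= bc_thr

    def role(row: pd.Series) -> str:
        if row["is_hub"] and row["is_bottleneck"]:
            return "date-hub"
        if row["is_hub"]:
            return "party-hub"
        if row["is_bottleneck"]:
            return "nonhub-bottleneck"
        return "other"

    out["role"] = out.apply(role, axis=1)
    out.attrs["dc_threshold"] = dc_thr
    out.attrs["bc_threshold"] = bc_thr
    return out


def summarize_backbone(backbone: BackboneNetwork) -> dict:
    """Node/link counts and mean DC/BC/CC over the backbone nodes."""
    if len(backbone.records) == 0:
        raise ValueError("backbone is empty")
    rec = backbone.records
    return {
        "n_nodes": len(rec),
        "n_links": backbone.graph.number_of_edges(),
        "mean_degree": float(rec["degree"].mean()),
        "mean_betweenness": float(rec["betweenness"].mean()),
        "mean_closeness": float(rec["closeness"].mean()),
    }
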