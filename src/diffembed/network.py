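"""Expression-weighted PPI networks from STRING-style edge lists.

The base network topology is fixed by a confidence-thresholded STRING
protein-links table; condition-specific expression enters only through edge
weights. For an edge (i, j) with log2 expression values x_i, x_j the raw
weight is

    w(i, j) = (x_i + x_j) / 2 + min(x_i, x_j)

(the mean plus the limiting partner), then min-max rescaled to [0, 2] per
condition network. The confidence score selects edges and never contributes
to the weight.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocessing import ExpressionProfile

__all__ = [
    "BaseNetwork",
    "WeightedPPINetwork",
    "load_string_edges",
    "restrict_to_expressed",
    "compute_edge_weights",
    "rescale_weights",
    "build_weighted_network",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BaseNetwork:
    """Fixed-topology interaction network.

    Simple undirected graph; every retained edge carries a ``combined_score``
    on the STRING 0–1000 scale. ``id_map`` records the protein -> gene
    renaming that was applied (empty if nodes were used verbatim).
    """

    graph: nx.Graph
    id_map: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclasses.dataclass
class WeightedPPINetwork:
    """One condition's weighted view of a shared base topology."""

    graph: nx.Graph  # edge attrs: weight (rescaled), raw_weight
    condition_label: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight_array(self) -> np.ndarray:
        return np.array([d["weight"] for _, _, d in self.graph.edges(data=True)])

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (*sorted((u, v)), d["raw_weight"], d["weight"])
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(
            sorted(rows), columns=["node_i", "node_j", "raw_weight", "rescaled_weight"]
        ).to_csv(path, sep="\t", index=False)


def _read_links_table(source: str | Path | io.IOBase | pd.DataFrame) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"edge list must have columns {sorted(required)}; got {list(df.columns)}"
        )
    for col in ("protein1", "protein2"):
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2  # +header +1-based
            raise ValueError(f"malformed edge list near line {line}: missing {col}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.isna().idxmax()) + 2
        raise ValueError(f"malformed edge list near line {line}: non-numeric score")
    df["combined_score"] = scores
    return df


def load_string_edges(
    source: str | Path | io.IOBase | pd.DataFrame,
    min_confidence: float = 0.4,
    id_map: pd.DataFrame | dict[str, str] | None = None,
) -> BaseNetwork:
    """Parse a STRING protein-links table into a base network.

    Scores are accepted on either the 0–1 or 0–1000 scale (auto-detected from
    the maximum value); ``min_confidence`` is always given on [0, 1]. Edges
    below threshold and self-loops are dropped; duplicate pairs keep the
    maximum score (with a warning when scores conflict). If ``id_map`` is
    given (protein_id -> gene_id table or dict), nodes are renamed to gene
    IDs; when several proteins map to one gene the first mapping per protein
    is kept and collisions are logged.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    df = _read_links_table(source)

    scale = 1.0 if (len(df) and df["combined_score"].max() <= 1.0) else 1000.0
    threshold = min_confidence * scale

    mapping: dict[str, str] = {}
    if id_map is not None:
        if isinstance(id_map, pd.DataFrame):
            pairs = id_map[["protein_id", "gene_id"]].itertuples(index=False)
        else:
            pairs = id_map.items()
        seen_genes: dict[str, str] = {}
        for pid, gid in pairs:
            if pid in mapping:
                logger.warning("duplicate mapping for protein %s; keeping first", pid)
                continue
            if gid in seen_genes:
                logger.warning(
                    "ID-mapping collision: proteins %s and %s both map to gene %s",
                    seen_genes[gid], pid, gid,
                )
            else:
                seen_genes[gid] = pid
            mapping[pid] = gid

    graph = nx.Graph()
    for p1, p2, score in df[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if score < threshold:
            continue
        u, v = str(p1), str(p2)
        if mapping:
            u, v = mapping.get(u, u), mapping.get(v, v)
        if u == v:
            continue  # self-loop (possibly induced by mapping)
        score_1000 = float(score) * (1000.0 / scale)
        if graph.has_edge(u, v):
            old = graph[u][v]["combined_score"]
            if old != score_1000:
                logger.warning("conflicting scores for edge (%s, %s); keeping max", u, v)
            graph[u][v]["combined_score"] = max(old, score_1000)
        else:
            graph.add_edge(u, v, combined_score=score_1000)
    return BaseNetwork(graph=graph, id_map=mapping)


def restrict_to_expressed(
    base: BaseNetwork, profiles: list[ExpressionProfile]
) -> BaseNetwork:
    """Drop nodes lacking an expression value in *any* profile.

    The resulting topology is shared by every condition of the comparison;
    disconnected components that appear are kept (heat diffusion is
    block-diagonal and well defined on them).
    """
    if len(profiles) < 2:
        raise ValueError("need at least the two profiles being compared")
    keep = set(base.graph.nodes)
    for profile in profiles:
        keep &= set(profile.values.index)
    if not keep:
        raise ValueError("no network node is expressed in every profile")
    sub = nx.Graph()
    sub.add_nodes_from(sorted(keep))
    sub.add_edges_from(
        (u, v, d) for u, v, d in base.graph.edges(data=True) if u in keep and v in keep
    )
    return BaseNetwork(graph=sub, id_map=base.id_map)


def compute_edge_weights(
    base: BaseNetwork, profile: ExpressionProfile
) -> dict[tuple[str, str], float]:
    """Raw edge weights (x_i + x_j)/2 + min(x_i, x_j) from log2 expression."""
    values = profile.values
    weights: dict[tuple[str, str], float] = {}
    for u, v in base.graph.edges:
        for node in (u, v):
            if node not in values.index:
                raise ValueError(f"no expression value for node {node!r}")
        xi, xj = float(values[u]), float(values[v])
        weights[tuple(sorted((u, v)))] = (xi + xj) / 2.0 + min(xi, xj)
    return weights


def rescale_weights(
    raw: dict[tuple[str, str], float], epsilon: float = 0.0
) -> dict[tuple[str, str], float]:
    """Affine min-max map of raw weights onto [0, 2].

    The minimum raw weight maps to exactly 0 (+ ``epsilon`` if a strictly
    positive offset is requested to keep every edge active) and the maximum
    to 2. Applied unconditionally, even if raw weights already lie in [0, 2].
    """
    if not raw:
        return {}
    values = np.array(list(raw.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("all raw edge weights are equal; [0, 2] rescale is undefined")
    scaled = 2.0 * (values - lo) / (hi - lo) + epsilon
    return dict(zip(raw.keys(), scaled.tolist()))


def build_weighted_network(
    base: BaseNetwork,
    profile: ExpressionProfile,
    epsilon: float = 0.0,
    shared_scale_with: ExpressionProfile | None = None,
) -> WeightedPPINetwork:
    """Weight one condition's network: raw mean+min weights, [0, 2] rescale.

    Rescaling is per-condition by default. ``shared_scale_with`` switches to
    a common scale across the two condition profiles (sensitivity analysis).
    """
    raw = compute_edge_weights(base, profile)
    if shared_scale_with is not None:
        other = compute_edge_weights(base, shared_scale_with)
        pool = np.array(list(raw.values()) + list(other.values()))
        lo, hi = pool.min(), pool.max()
        if hi == lo:
            raise ValueError("all raw edge weights are equal; [0, 2] rescale is undefined")
        rescaled = {e: 2.0 * (w - lo) / (hi - lo) + epsilon for e, w in raw.items()}
    else:
        rescaled = rescale_weights(raw, epsilon=epsilon)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(base.graph.nodes))
    for (u, v), w in raw.items():
        graph.add_edge(u, v, raw_weight=w, weight=rescaled[(u, v)])
    return WeightedPPINetwork(graph=graph, condition_label=profile.condition_label)
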