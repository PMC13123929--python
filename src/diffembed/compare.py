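"""Joint dimension reduction and per-node embedding distances.

The two conditions' embeddings are reduced with a *single* PCA fitted on the
row-stacked matrix of both sets (mean-centred, no variance scaling, full SVD
solver). A joint fit is essential: separately fitted components carry
per-fit sign/rotation ambiguity, making cross-condition coordinates
incomparable. Per-node differential signal is the Euclidean distance between
the node's two reduced coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .graphwave import NodeEmbeddingSet

__all__ = ["DistanceTable", "joint_pca", "node_distances", "expression_distance_correlation"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DistanceTable:
    """Per-node embedding distance between two conditions.

    ``table`` has one row per shared node: distance plus optional per-
    condition mean log2 expression columns. ``explained_variance`` is the
    fraction of stacked-embedding variance retained by the kept components.
    """

    table: pd.DataFrame  # index node_id; columns: distance[, mean_expr_*]
    explained_variance: float
    comparison_label: str = ""

    def __post_init__(self) -> None:
        if (self.table["distance"] < 0).any():
            raise ValueError("distances must be non-negative")
        if not 0 <= self.explained_variance <= 1 + 1e-12:
            raise ValueError("explained_variance must lie in [0, 1]")

    @property
    def distances(self) -> pd.Series:
        return self.table["distance"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")
        meta = {"comparison": self.comparison_label,
                "explained_variance": self.explained_variance}
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def joint_pca(
    emb_a: NodeEmbeddingSet, emb_b: NodeEmbeddingSet, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project both embedding sets into one shared principal subspace.

    Components are fitted on the stacked (2N x d) matrix so coordinates are
    directly comparable across conditions. Returns (reduced_a, reduced_b,
    explained_variance_fraction); a warning is logged if the retained
    components explain less than 90% of variance (diagnostic, not an error).
    """
    if emb_a.node_ids != emb_b.node_ids:
        raise ValueError("embedding sets must cover the same nodes in the same order")
    if emb_a.n_dims != emb_b.n_dims:
        raise ValueError("embedding sets must share dimensionality")
    if n_components > emb_a.n_dims:
        raise ValueError("n_components exceeds embedding dimension")
    stacked = np.vstack([emb_a.vectors, emb_b.vectors])
    pca = PCA(n_components=n_components, svd_solver="full")
    reduced = pca.fit_transform(stacked)
    explained = float(pca.explained_variance_ratio_.sum())
    if explained < 0.90:
        logger.warning(
            "retained components explain only %.1f%% of embedding variance",
            100 * explained,
        )
    n = len(emb_a.node_ids)
    return reduced[:n], reduced[n:], explained


def node_distances(
    emb_a: NodeEmbeddingSet,
    emb_b: NodeEmbeddingSet,
    n_components: int = 2,
    mean_expression: dict[str, pd.Series] | None = None,
    comparison_label: str = "",
) -> DistanceTable:
    """Euclidean distance per node between jointly reduced embeddings."""
    red_a, red_b, explained = joint_pca(emb_a, emb_b, n_components=n_components)
    dist = np.linalg.norm(red_a - red_b, axis=1)
    table = pd.DataFrame({"distance": dist},
                         index=pd.Index(emb_a.node_ids, name="node_id"))
    if mean_expression:
        for label, series in mean_expression.items():
            missing = set(table.index) - set(series.index)
            if missing:
                raise ValueError(f"expression missing for nodes: {sorted(missing)[:5]}")
            table[f"mean_expr_{label}"] = series.reindex(table.index)
    if not comparison_label:
        comparison_label = f"{emb_a.condition_label}_vs_{emb_b.condition_label}"
    return DistanceTable(table=table, explained_variance=explained,
                         comparison_label=comparison_label)


def expression_distance_correlation(
    expression: pd.Series, distances: pd.Series
) -> tuple[float, int]:
    """Pearson correlation between mean expression and embedding distance.

    A diagnostic for expression-level bias: large |r| indicates distances
    track raw expression rather than network context. Returns (r, n).
    """
    shared = expression.index.intersection(distances.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared nodes for a correlation")
    x = expression.reindex(shared).to_numpy(dtype=float)
    y = distances.reindex(shared).to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(len(shared))
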