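"""IQR outlier calling and control–control false-positive filtering.

Nodes whose embedding distance exceeds an interquartile-range based
threshold are flagged as outliers. To remove expression-level artifacts,
the identical pipeline is rerun on two halves of the control replicates over
the same base topology; nodes outlying in *both* the disease–control and
control–control comparisons (the latter judged at the disease-analysis
threshold) are discarded as false positives. Surviving disease outliers are
the candidate set.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .compare import DistanceTable, node_distances
from .graphwave import EmbeddingConfig, embed_pair
from .network import BaseNetwork, build_weighted_network
from .preprocessing import CountMatrix, DEFAULT_FLOOR, log_transform

__all__ = [
    "OutlierCall",
    "CandidateSet",
    "iqr_threshold",
    "call_outliers",
    "split_control_samples",
    "control_control_analysis",
    "filter_false_positives",
]

Rule = Literal["literal_iqr", "tukey_fence"]


@dataclasses.dataclass
class OutlierCall:
    """One outlier determination: the threshold, the rule, and the flagged set."""

    threshold: float
    rule: Rule
    outliers: frozenset[str]
    k: float = 1.5
    quartile_method: str = "linear"


@dataclasses.dataclass
class CandidateSet:
    """Disease outliers partitioned into false positives and candidates."""

    disease_outliers: frozenset[str]
    control_outliers: frozenset[str]

    @property
    def false_positives(self) -> frozenset[str]:
        return self.disease_outliers & self.control_outliers

    @property
    def candidates(self) -> frozenset[str]:
        return self.disease_outliers - self.control_outliers

    def summary(self) -> dict[str, int]:
        return {
            "disease_outliers": len(self.disease_outliers),
            "control_outliers": len(self.control_outliers),
            "false_positives": len(self.false_positives),
            "candidates": len(self.candidates),
        }


def iqr_threshold(
    distances: pd.Series | np.ndarray,
    k: float = 1.5,
    rule: Rule = "literal_iqr",
) -> float:
    """Distance cutoff from the interquartile range.

    ``literal_iqr`` uses k * IQR directly on the distance scale (the default
    reading of "greater than 1.5 x IQR"); ``tukey_fence`` uses the upper
    Tukey fence Q3 + k * IQR. Quartiles are linearly interpolated order
    statistics.
    """
    values = np.asarray(distances, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 distances to form quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if rule == "literal_iqr":
        return float(k * iqr)
    if rule == "tukey_fence":
        return float(q3 + k * iqr)
    raise ValueError(f"unknown rule {rule!r}")


def call_outliers(
    table: DistanceTable,
    threshold: float | None = None,
    k: float = 1.5,
    rule: Rule = "literal_iqr",
) -> OutlierCall:
    """Flag nodes with distance strictly greater than the threshold.

    If ``threshold`` is not given it is derived from this table's own
    distances via ``iqr_threshold``. The inequality is strict: a node
    exactly at the threshold is not an outlier.
    """
    if threshold is None:
        threshold = iqr_threshold(table.distances, k=k, rule=rule)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    flagged = table.distances.index[table.distances > threshold]
    return OutlierCall(threshold=float(threshold), rule=rule,
                       outliers=frozenset(flagged), k=k)


def split_control_samples(
    samples: list[str], split: str = "half", seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Split control replicates into two groups for the null comparison.

    ``half`` (default) is deterministic: first half vs last half by sample
    order. ``random`` shuffles with the given seed before halving.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 control replicates to split")
    order = list(samples)
    if split == "random":
        if seed is None:
            raise ValueError("random split requires a seed")
        rng = np.random.default_rng(seed)
        order = [order[i] for i in rng.permutation(len(order))]
    elif split != "half":
        raise ValueError(f"unknown split spec {split!r}")
    mid = len(order) // 2
    return order[:mid], order[mid:]


def control_control_analysis(
    matrix: CountMatrix,
    control_group: str,
    base: BaseNetwork,
    config: EmbeddingConfig = EmbeddingConfig(),
    floor: float = DEFAULT_FLOOR,
    split: str = "half",
    seed: int | None = None,
    n_components: int = 2,
) -> DistanceTable:
    """Run the identical pipeline on two halves of the control replicates.

    Uses the *same restricted base network* as the disease comparison, so
    control–control distances are directly comparable to disease–control
    distances.
    """
    samples = matrix.samples_in_group(control_group)
    half_a, half_b = split_control_samples(samples, split=split, seed=seed)
    networks = []
    for label, half in (("control_A", half_a), ("control_B", half_b)):
        means = matrix.counts[half].mean(axis=1)
        profile = log_transform(means, floor=floor, condition_label=label)
        networks.append(build_weighted_network(base, profile))
    emb_a, emb_b = embed_pair(*networks, config=config)
    return node_distances(emb_a, emb_b, n_components=n_components,
                          comparison_label="control_A_vs_control_B")


def filter_false_positives(
    disease_call: OutlierCall, control_table: DistanceTable
) -> CandidateSet:
    """Remove disease outliers that also outlie in the control–control run.

    Control outliers are called with the *disease-analysis* threshold, not a
    threshold derived from the control–control distances.
    """
    control_call = call_outliers(control_table, threshold=disease_call.threshold,
                                 k=disease_call.k, rule=disease_call.rule)
    return CandidateSet(disease_outliers=disease_call.outliers,
                        control_outliers=control_call.outliers)
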