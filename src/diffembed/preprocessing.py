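"""Replicate aggregation and log2 transformation of RNA-seq counts.

Per-condition expression is the arithmetic mean of replicate read counts,
taken to base-2 log. Genes with zero counts across all replicates receive a
floor value of 0.125 before the transform (log2(0.125) = -3); nonzero means
below the floor are log-transformed as-is.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ExpressionProfile", "aggregate_replicates", "log_transform"]

DEFAULT_FLOOR = 0.125


@dataclasses.dataclass
class CountMatrix:
    """Gene x sample count matrix with a sample -> group mapping.

    Counts are accepted as non-negative reals (expected counts from upstream
    quantifiers are legal); integrality is not enforced.
    """

    counts: pd.DataFrame  # genes x samples
    group_of: pd.Series  # sample_id -> group label

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.group_of.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str) -> list[str]:
        samples = [s for s in self.counts.columns if self.group_of[s] == group]
        if not samples:
            raise ValueError(f"unknown or empty group label: {group!r}")
        return samples

    @classmethod
    def from_tsv(cls, counts_path: str | Path, groups_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t")
        return cls(counts=counts, group_of=groups.set_index("sample_id")["group"])


@dataclasses.dataclass
class ExpressionProfile:
    """Per-gene log2 expression for one condition.

    ``floor_applied`` records exactly the genes whose zero mean was replaced
    by the floor before the log transform.
    """

    values: pd.Series  # gene_id -> log2 expression
    condition_label: str
    floor_applied: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression profile contains non-finite values")

    def __getitem__(self, gene_id: str) -> float:
        return float(self.values[gene_id])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"log2_value": self.values,
             "floored": [g in self.floor_applied for g in self.values.index]}
        )
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def aggregate_replicates(matrix: CountMatrix, group: str) -> pd.Series:
    """Mean count per gene over the replicates of one group."""
    samples = matrix.samples_in_group(group)
    return matrix.counts[samples].mean(axis=1)


def log_transform(
    means: pd.Series,
    floor: float = DEFAULT_FLOOR,
    condition_label: str = "",
    clamp_below_floor: bool = False,
) -> ExpressionProfile:
    """Base-2 log transform of aggregated mean counts.

    Zero means get ``log2(floor)``; positive means below the floor are
    transformed as-is unless ``clamp_below_floor`` is set (robustness switch,
    off by default).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    arr = means.to_numpy(dtype=float)
    if (arr < 0).any():
        bad = means.index[arr < 0][0]
        raise ValueError(f"negative mean count for gene {bad!r}")
    zero = arr == 0
    if clamp_below_floor:
        floored_mask = arr < floor
    else:
        floored_mask = zero
    out = np.where(floored_mask, np.log2(floor), np.log2(np.where(zero, 1.0, arr)))
    values = pd.Series(out, index=means.index)
    return ExpressionProfile(
        values=values,
        condition_label=condition_label,
        floor_applied=frozenset(means.index[floored_mask]),
    )


def condition_profile(
    matrix: CountMatrix, group: str, floor: float = DEFAULT_FLOOR
) -> ExpressionProfile:
    """Aggregate one group's replicates and log-transform in a single step."""
    return log_transform(aggregate_replicates(matrix, group), floor=floor, condition_label=group)
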