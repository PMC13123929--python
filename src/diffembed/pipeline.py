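"""End-to-end orchestration of one disease-vs-control comparison.

Stage order: preprocess counts -> build and restrict the base network ->
condition-specific edge weights -> spectral-wavelet embeddings -> joint PCA
+ per-node distances -> IQR outlier calling -> control–control
false-positive filtering -> candidate set. Every tunable is captured in a
run manifest so a run can be reproduced from the manifest alone; the
analysis stages themselves are deterministic and seed-free (only the
optional random control split consumes a seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .compare import DistanceTable, expression_distance_correlation, node_distances
from .graphwave import EmbeddingConfig, embed_pair
from .network import BaseNetwork, build_weighted_network, load_string_edges, restrict_to_expressed
from .outliers import (
    CandidateSet,
    OutlierCall,
    call_outliers,
    control_control_analysis,
    filter_false_positives,
)
from .preprocessing import CountMatrix, DEFAULT_FLOOR, aggregate_replicates, log_transform
from .stats import OverlapTestResult, build_overlap_table, fisher_exact

__all__ = ["RunConfig", "ComparisonResult", "run_comparison", "run_comparison_from_files",
           "run_overlap_report"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Every tunable of one comparison, with explicit defaults."""

    disease_group: str = "disease"
    control_group: str = "control"
    floor: float = DEFAULT_FLOOR
    min_confidence: float = 0.4
    embedding: EmbeddingConfig = dataclasses.field(default_factory=EmbeddingConfig)
    n_components: int = 2
    outlier_rule: str = "literal_iqr"
    outlier_k: float = 1.5
    control_split: str = "half"
    split_seed: int | None = None

    def manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["embedding"]["t_grid"] = list(self.embedding.t_grid)
        return d


@dataclasses.dataclass
class ComparisonResult:
    """Outputs of one full comparison run."""

    distance_table: DistanceTable
    control_table: DistanceTable
    outlier_call: OutlierCall
    candidate_set: CandidateSet
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.distance_table.to_tsv(out / "distances.tsv")
        self.control_table.to_tsv(out / "control_control_distances.tsv")
        flags = pd.DataFrame(
            {
                "distance": self.distance_table.distances,
                "outlier": [n in self.outlier_call.outliers
                            for n in self.distance_table.table.index],
                "false_positive": [n in self.candidate_set.false_positives
                                   for n in self.distance_table.table.index],
                "candidate": [n in self.candidate_set.candidates
                              for n in self.distance_table.table.index],
            }
        )
        flags.index.name = "node_id"
        flags.to_csv(out / "candidates.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def run_comparison(
    matrix: CountMatrix,
    base: BaseNetwork,
    config: RunConfig = RunConfig(),
) -> ComparisonResult:
    """Run the full differential-embedding analysis for one comparison."""
    stage = "preprocessing"
    try:
        disease_means = aggregate_replicates(matrix, config.disease_group)
        control_means = aggregate_replicates(matrix, config.control_group)
        disease_profile = log_transform(disease_means, floor=config.floor,
                                        condition_label=config.disease_group)
        control_profile = log_transform(control_means, floor=config.floor,
                                        condition_label=config.control_group)

        stage = "network restriction"
        restricted = restrict_to_expressed(base, [disease_profile, control_profile])
        logger.info("restricted network: %d nodes, %d edges",
                    restricted.graph.number_of_nodes(), restricted.graph.number_of_edges())

        stage = "edge weighting"
        disease_net = build_weighted_network(restricted, disease_profile)
        control_net = build_weighted_network(restricted, control_profile)

        stage = "embedding"
        emb_disease, emb_control = embed_pair(disease_net, control_net, config.embedding)

        stage = "distance calculation"
        mean_expr = {
            config.disease_group: disease_profile.values,
            config.control_group: control_profile.values,
        }
        table = node_distances(emb_disease, emb_control,
                               n_components=config.n_components,
                               mean_expression=mean_expr)
        r_expr, _ = expression_distance_correlation(control_profile.values, table.distances)
        logger.info("explained variance %.3f; expression-distance r = %.4f",
                    table.explained_variance, r_expr)

        stage = "outlier detection"
        call = call_outliers(table, k=config.outlier_k, rule=config.outlier_rule)
        logger.info("threshold %.4f (%s): %d outliers",
                    call.threshold, call.rule, len(call.outliers))

        stage = "false-positive analysis"
        control_table = control_control_analysis(
            matrix, config.control_group, restricted,
            config=config.embedding, floor=config.floor,
            split=config.control_split, seed=config.split_seed,
            n_components=config.n_components,
        )
        candidates = filter_false_positives(call, control_table)
        logger.info("candidates: %s", candidates.summary())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    manifest = {
        "config": config.manifest_dict(),
        "embedding_fingerprints": {
            config.disease_group: emb_disease.fingerprint,
            config.control_group: emb_control.fingerprint,
        },
        "stage_counts": {
            "nodes": restricted.graph.number_of_nodes(),
            "edges": restricted.graph.number_of_edges(),
            **candidates.summary(),
        },
        "diagnostics": {
            "explained_variance": table.explained_variance,
            "expression_distance_r": r_expr,
            "mean_distance": float(table.distances.mean()),
            "mean_control_control_distance": float(control_table.distances.mean()),
            "threshold": call.threshold,
        },
    }
    return ComparisonResult(distance_table=table, control_table=control_table,
                            outlier_call=call, candidate_set=candidates,
                            manifest=manifest)


def run_comparison_from_files(
    counts_path: str | Path,
    groups_path: str | Path,
    edges_path: str | Path,
    mapping_path: str | Path | None = None,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> ComparisonResult:
    """File-based front end to :func:`run_comparison`.

    Validates that every referenced file exists before any work starts.
    """
    paths = [counts_path, groups_path, edges_path]
    if mapping_path is not None:
        paths.append(mapping_path)
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"input files not found: {missing}")
    matrix = CountMatrix.from_tsv(counts_path, groups_path)
    id_map = pd.read_csv(mapping_path, sep="\t") if mapping_path is not None else None
    base = load_string_edges(edges_path, min_confidence=config.min_confidence, id_map=id_map)
    try:
        result = run_comparison(matrix, base, config)
    except RuntimeError:
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text("run aborted; see logs\n")
        raise
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_overlap_report(
    candidates: set[str],
    gene_lists: Mapping[str, set[str]],
    background: set[str],
) -> dict[str, OverlapTestResult]:
    """Fisher exact overlap test of the candidate set against each gene list."""
    if not candidates:
        raise ValueError("candidate set is empty")
    report = {}
    for name, genes in gene_lists.items():
        if not genes:
            raise ValueError(f"gene list {name!r} is empty")
        table = build_overlap_table(candidates, genes, background)
        report[name] = fisher_exact(table)
    return report
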