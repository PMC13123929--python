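"""Synthetic PPI graphs and two-condition RNA-seq count matrices.

Generates the inputs the differential-embedding pipeline consumes — a
scale-free (or duplication-divergence / Erdős–Rényi) interaction graph with
STRING-style confidence scores, and replicate negative-binomial count
matrices for a control and a disease condition — with a *planted deletion*:
a chosen gene set whose counts are forced to zero in the disease condition,
optionally perturbing the expression of its 1-hop network neighbours. This
emulates an engineered chromosomal deletion and lets candidate recovery be
measured against a known ground truth without any external download.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticScenario",
    "generate_graph",
    "generate_counts",
    "ground_truth",
    "hub_module",
    "write_scenario_files",
]

GraphModel = Literal["scale_free", "duplication_divergence", "erdos_renyi"]


def _gene_id(i: int) -> str:
    return f"G{i + 1:06d}"


def _protein_id(i: int) -> str:
    return f"P{i + 1:06d}"


@dataclasses.dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic two-condition experiment.

    Parameters
    ----------
    n_genes:
        Number of genes (= graph nodes).
    graph_model:
        ``scale_free`` (Barabási–Albert preferential attachment),
        ``duplication_divergence`` or ``erdos_renyi``.
    attachment_or_density:
        Model parameter: attachment count *m* for scale-free, retention
        probability for duplication-divergence, edge probability for
        Erdős–Rényi.
    n_replicates_per_condition:
        Replicate count per condition (default 6).
    nb_mean_log_mu, nb_mean_log_sigma:
        Parameters of the log-normal distribution of per-gene baseline mean
        counts (natural-log scale).
    nb_dispersion:
        Negative-binomial size parameter ``r`` (variance = mu + mu^2/r);
        ``r -> inf`` approaches Poisson.
    deletion_genes:
        Gene IDs whose disease counts are forced to zero.
    neighbor_effect:
        Multiplicative fold-change applied to the disease-condition mean of
        every 1-hop neighbour of a deleted gene (1.0 = no effect).
    seed:
        RNG seed; identical scenarios reproduce byte-identical outputs.
    """

    n_genes: int
    graph_model: GraphModel = "scale_free"
    attachment_or_density: float = 2.0
    n_replicates_per_condition: int = 6
    nb_mean_log_mu: float = 4.0
    nb_mean_log_sigma: float = 1.5
    nb_dispersion: float = 10.0
    deletion_genes: frozenset[str] = frozenset()
    neighbor_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.neighbor_effect <= 0:
            raise ValueError("neighbor_effect must be positive (1.0 = none)")


def generate_graph(scenario: SyntheticScenario) -> tuple[nx.Graph, pd.DataFrame, pd.DataFrame]:
    """Generate the interaction graph for a scenario.

    Returns
    -------
    graph:
        Simple undirected graph on gene IDs ``G000001...``; each edge carries
        a synthetic STRING-style ``combined_score`` in [400, 999].
    edges:
        STRING protein-links dialect table (protein1, protein2,
        combined_score) using protein IDs.
    id_map:
        Two-column (protein_id, gene_id) mapping table.
    """
    n = scenario.n_genes
    p = scenario.attachment_or_density
    seed = int(scenario.seed) % (2**31)
    if scenario.graph_model == "scale_free":
        m = int(round(p))
        if not 1 <= m < n:
            raise ValueError(f"scale_free attachment must be in [1, n_genes): got {p}")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    elif scenario.graph_model == "duplication_divergence":
        if not 0 < p <= 1:
            raise ValueError(f"duplication_divergence retention must be in (0, 1]: got {p}")
        g = nx.duplication_divergence_graph(n, p, seed=seed)
    elif scenario.graph_model == "erdos_renyi":
        if not 0 <= p <= 1:
            raise ValueError(f"erdos_renyi edge probability must be in [0, 1]: got {p}")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown graph model {scenario.graph_model!r}")

    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_nodes_from(_gene_id(i) for i in range(n))
    edge_rows = []
    for u, v in sorted(map(sorted, g.edges())):
        score = int(rng.integers(400, 1000))
        graph.add_edge(_gene_id(u), _gene_id(v), combined_score=score)
        edge_rows.append((_protein_id(u), _protein_id(v), score))

    unknown = set(scenario.deletion_genes) - set(graph.nodes)
    if unknown:
        raise ValueError(f"deletion genes not in the gene universe: {sorted(unknown)}")

    edges = pd.DataFrame(edge_rows, columns=["protein1", "protein2", "combined_score"])
    id_map = pd.DataFrame(
        {"protein_id": [_protein_id(i) for i in range(n)],
         "gene_id": [_gene_id(i) for i in range(n)]}
    )
    return graph, edges, id_map


def generate_counts(
    scenario: SyntheticScenario, graph: nx.Graph
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw replicate count matrices for control and disease conditions.

    Per-gene baseline means are log-normal; counts are negative-binomial
    around those means. In the disease condition, deleted genes are forced
    to zero counts and 1-hop neighbours of deleted genes have their means
    multiplied by ``neighbor_effect``. All other genes share baselines
    across conditions.
    """
    genes = sorted(graph.nodes)
    missing = set(scenario.deletion_genes) - set(genes)
    if missing:
        raise ValueError(f"deletion genes absent from graph: {sorted(missing)}")

    rng = np.random.default_rng(int(scenario.seed) % (2**31))
    n = len(genes)
    reps = scenario.n_replicates_per_condition
    mu = rng.lognormal(scenario.nb_mean_log_mu, scenario.nb_mean_log_sigma, size=n)

    truth = ground_truth(scenario, graph)
    idx = {g: i for i, g in enumerate(genes)}
    mu_disease = mu.copy()
    for g in truth["neighbor"]:
        mu_disease[idx[g]] *= scenario.neighbor_effect
    deleted_mask = np.zeros(n, dtype=bool)
    for g in truth["deleted"]:
        deleted_mask[idx[g]] = True

    r = scenario.nb_dispersion

    def draw(means: np.ndarray) -> np.ndarray:
        # NB(mean=mu, size=r): numpy parametrisation p = r / (r + mu)
        p = r / (r + means)
        return rng.negative_binomial(r, p[:, None], size=(n, reps))

    control = draw(mu)
    disease = draw(mu_disease)
    disease[deleted_mask, :] = 0

    control_df = pd.DataFrame(
        control, index=pd.Index(genes, name="gene_id"),
        columns=[f"control_{i + 1}" for i in range(reps)],
    )
    disease_df = pd.DataFrame(
        disease, index=pd.Index(genes, name="gene_id"),
        columns=[f"disease_{i + 1}" for i in range(reps)],
    )
    return control_df, disease_df


def ground_truth(scenario: SyntheticScenario, graph: nx.Graph) -> dict[str, set[str]]:
    """Partition the gene universe into deleted / neighbor / unaffected sets."""
    deleted = set(scenario.deletion_genes)
    missing = deleted - set(graph.nodes)
    if missing:
        raise ValueError(f"deletion genes absent from graph: {sorted(missing)}")
    neighbor: set[str] = set()
    for g in deleted:
        neighbor.update(graph.neighbors(g))
    neighbor -= deleted
    unaffected = set(graph.nodes) - deleted - neighbor
    return {"deleted": deleted, "neighbor": neighbor, "unaffected": unaffected}


def hub_module(graph: nx.Graph, size: int) -> frozenset[str]:
    """The ``size`` highest-degree genes (ties broken by gene ID).

    Convenience for planting a deletion on a hub module, mimicking the loss
    of a well-connected chromosomal region.
    """
    ranked = sorted(graph.nodes, key=lambda g: (-graph.degree(g), g))
    return frozenset(ranked[:size])


def write_scenario_files(
    scenario: SyntheticScenario,
    out_dir: str | Path,
    disease_label: str = "disease",
    control_label: str = "control",
) -> dict[str, Path]:
    """Materialise one scenario as the on-disk formats the pipeline reads.

    Writes counts TSV (gene rows, replicate columns), sample-to-group TSV,
    STRING-dialect edge list, protein/gene mapping TSV and ground-truth TSV.
    Returns the path of each file by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, edges, id_map = generate_graph(scenario)
    control_df, disease_df = generate_counts(scenario, graph)
    truth = ground_truth(scenario, graph)

    counts = pd.concat([control_df, disease_df], axis=1)
    paths = {
        "counts": out / "counts.tsv",
        "groups": out / "groups.tsv",
        "edges": out / "protein_links.txt",
        "mapping": out / "id_mapping.tsv",
        "truth": out / "ground_truth.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    groups = pd.DataFrame(
        {"sample_id": list(counts.columns),
         "group": [control_label] * control_df.shape[1] + [disease_label] * disease_df.shape[1]}
    )
    groups.to_csv(paths["groups"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep=" ", index=False)
    id_map.to_csv(paths["mapping"], sep="\t", index=False)
    truth_df = pd.DataFrame(
        sorted((g, label) for label, genes in truth.items() for g in genes),
        columns=["gene_id", "label"],
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
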