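"""Deterministic structural node embeddings via spectral graph wavelets.

Heat-kernel wavelets on the weighted graph Laplacian, summarised per node by
the empirical characteristic function of its wavelet coefficients
(the GraphWave construction):

    Psi(s) = U diag(exp(-s * lambda)) U^T          (heat kernel at scale s)
    phi_a(t) = (1/N) * sum_m exp(i * t * Psi(s)[m, a])

The embedding of node ``a`` concatenates [Re phi_a(t), Im phi_a(t)] over a
grid of t values and a set of diffusion scales. Because Psi is a function of
L alone, the embedding is deterministic, invariant to eigenvector sign/order
ambiguity, and equivariant under node relabelling — nodes in the same
automorphism orbit receive identical vectors.

Two backends: exact dense eigendecomposition (reference path, graphs up to a
few thousand nodes) and a Chebyshev polynomial approximation of exp(-sL) for
larger graphs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import scipy.special

from .network import WeightedPPINetwork

__all__ = [
    "EmbeddingConfig",
    "NodeEmbeddingSet",
    "build_laplacian",
    "select_scales",
    "heat_wavelets",
    "characteristic_embedding",
    "embed_network",
    "embed_pair",
]

Backend = Literal["exact", "chebyshev"]


@dataclasses.dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding hyper-parameters.

    The default decomposition of the 100-dimensional embedding is 2
    auto-selected diffusion scales x 25 evaluation points on [0, 100] x the
    (Re, Im) pair. ``scales`` may be an explicit list to bypass auto
    selection. ``eta_pair = (eta_max, eta_min)`` controls the automatic
    scale range: s_min = -ln(eta_max)/sqrt(lambda_2 * lambda_N),
    s_max = -ln(eta_min)/sqrt(lambda_2 * lambda_N), with scales spaced
    geometrically in between.
    """

    n_scales: int = 2
    scales: tuple[float, ...] | None = None
    t_grid: tuple[float, ...] = tuple(np.linspace(0.0, 100.0, 25))
    backend: Backend = "exact"
    chebyshev_order: int = 50
    eta_pair: tuple[float, float] = (0.95, 0.70)
    normalized_laplacian: bool = False

    @property
    def n_dims(self) -> int:
        n_s = len(self.scales) if self.scales is not None else self.n_scales
        return 2 * n_s * len(self.t_grid)

    def __post_init__(self) -> None:
        if self.scales is not None and any(s <= 0 for s in self.scales):
            raise ValueError("diffusion scales must be strictly positive")
        if self.chebyshev_order < 1:
            raise ValueError("chebyshev_order must be >= 1")
        eta_max, eta_min = self.eta_pair
        if not (0 < eta_min < eta_max < 1):
            raise ValueError("eta_pair must satisfy 0 < eta_min < eta_max < 1")

    def fingerprint(self, extra: str = "") -> str:
        payload = json.dumps(
            {**dataclasses.asdict(self), "t_grid": list(self.t_grid), "extra": extra},
            sort_keys=True, default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class NodeEmbeddingSet:
    """Per-node embedding vectors for one condition network."""

    node_ids: list[str]
    vectors: np.ndarray  # (n_nodes, n_dims)
    condition_label: str
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("one embedding row per node required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def n_dims(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"e{k}" for k in range(self.n_dims)]
        return pd.DataFrame(self.vectors, index=pd.Index(self.node_ids, name="node_id"),
                            columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(json.dumps(
            {"condition": self.condition_label, "fingerprint": self.fingerprint,
             "n_dims": self.n_dims}, indent=2))


def build_laplacian(
    network: WeightedPPINetwork, normalized: bool = False
) -> tuple[sp.csr_array, list[str]]:
    """Weighted graph Laplacian L = D - W over the sorted node list.

    Zero-weight edges contribute nothing; isolated nodes yield zero
    rows/columns. Returns (L, nodelist).
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("network has no nodes")
    if normalized:
        lap = nx.normalized_laplacian_matrix(network.graph, nodelist=nodes, weight="weight")
    else:
        lap = nx.laplacian_matrix(network.graph, nodelist=nodes, weight="weight")
    return sp.csr_array(lap.astype(float)), nodes


def _eigendecompose(L: sp.csr_array) -> tuple[np.ndarray, np.ndarray]:
    lam, U = scipy.linalg.eigh(L.toarray())
    return np.clip(lam, 0.0, None), U


def _spectral_extremes(
    L: sp.csr_array, n_components: int, eigenvalues: np.ndarray | None = None
) -> tuple[float, float]:
    """(lambda_2, lambda_max): smallest nonzero and largest eigenvalue."""
    if eigenvalues is not None:
        lam = np.asarray(eigenvalues)
        nonzero = lam[lam > 1e-10]
        if nonzero.size == 0:
            raise ValueError(
                "Laplacian has no nonzero eigenvalue (edgeless graph); "
                "supply diffusion scales explicitly"
            )
        return float(nonzero.min()), float(lam.max())
    n = L.shape[0]
    if n <= 200:  # dense path: tiny problems trip ARPACK's k < n constraints
        return _spectral_extremes(L, n_components,
                                  eigenvalues=scipy.linalg.eigvalsh(L.toarray()))
    v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector: deterministic
    lam_max = float(spla.eigsh(L, k=1, which="LA", v0=v0, return_eigenvectors=False)[0])
    if lam_max <= 1e-10:
        raise ValueError(
            "Laplacian has no nonzero eigenvalue (edgeless graph); "
            "supply diffusion scales explicitly"
        )
    k = min(n_components + 1, n - 1)
    small = spla.eigsh(L, k=k, sigma=-1e-3, which="LM", v0=v0, return_eigenvectors=False)
    nonzero = small[small > 1e-8 * lam_max]
    lam2 = float(nonzero.min()) if nonzero.size else lam_max
    return lam2, lam_max


def select_scales(
    L: sp.csr_array,
    n_scales: int = 2,
    eta_pair: tuple[float, float] = (0.95, 0.70),
    n_components: int | None = None,
    eigenvalues: np.ndarray | None = None,
) -> list[float]:
    """Automatic diffusion scales from the spectral range.

    Uses the geometric mean of the smallest nonzero and largest eigenvalue:
    scales span [-ln(eta_max), -ln(eta_min)] / sqrt(lambda_2 * lambda_N),
    geometrically spaced. Deterministic.
    """
    eta_max, eta_min = eta_pair
    if n_components is None:
        n_components = sp.csgraph.connected_components(L, directed=False,
                                                       return_labels=False)
    lam2, lam_max = _spectral_extremes(L, n_components, eigenvalues)
    ref = np.sqrt(lam2 * lam_max)
    s_min = -np.log(eta_max) / ref
    s_max = -np.log(eta_min) / ref
    if n_scales == 1:
        return [float(np.sqrt(s_min * s_max))]
    return list(np.geomspace(s_min, s_max, n_scales))


def heat_wavelets(
    L: sp.csr_array,
    s: float,
    backend: Backend = "exact",
    chebyshev_order: int = 50,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Heat-kernel wavelet matrix Psi(s) = exp(-s L).

    Column ``a`` is the heat distribution diffused from node ``a`` after time
    ``s``; each column sums to 1 per connected component and entries lie in
    [0, 1]. ``eig`` optionally reuses a precomputed (eigenvalues,
    eigenvectors) pair on the exact backend.
    """
    if s <= 0:
        raise ValueError("scale s must be strictly positive")
    if backend == "exact":
        lam, U = eig if eig is not None else _eigendecompose(L)
        return (U * np.exp(-s * lam)) @ U.T
    if backend == "chebyshev":
        return _chebyshev_heat_kernel(L, s, chebyshev_order)
    raise ValueError(f"unknown backend {backend!r}")


def _chebyshev_heat_kernel(L: sp.csr_array, s: float, order: int) -> np.ndarray:
    """Chebyshev expansion of exp(-s L) on the spectral interval [0, lmax].

    With x = (lmax/2)(y + 1), exp(-s x) = e^{-a} [I_0(a) + 2 sum_k (-1)^k
    I_k(a) T_k(y)] where a = s*lmax/2 and I_k is the modified Bessel
    function (computed via the scaled variant for stability).
    """
    if order < 1:
        raise ValueError("chebyshev_order must be >= 1")
    n = L.shape[0]
    v0 = np.full(n, 1.0 / np.sqrt(n))
    if n > 2:
        lmax = float(spla.eigsh(L, k=1, which="LA", v0=v0, return_eigenvectors=False)[0])
    else:
        lmax = float(np.max(scipy.linalg.eigvalsh(L.toarray())))
    if lmax <= 0:
        return np.eye(n)
    lmax *= 1.01  # guard: keep the true spectrum inside the expansion interval
    a = s * lmax / 2.0
    # coefficients c_k = 2 (-1)^k e^{-a} I_k(a); ive(k, a) = I_k(a) e^{-a}
    ks = np.arange(order + 1)
    coef = 2.0 * ((-1.0) ** ks) * scipy.special.ive(ks, a)
    coef[0] /= 2.0
    # T_k(Y) recurrence with Y = (2/lmax) L - I applied to the identity
    Y = sp.csr_array((2.0 / lmax) * L - sp.identity(n, format="csr"))
    T_prev = np.eye(n)
    T_cur = Y @ T_prev
    acc = coef[0] * T_prev + coef[1] * T_cur
    for k in range(2, order + 1):
        T_next = 2.0 * (Y @ T_cur) - T_prev
        acc += coef[k] * T_next
        T_prev, T_cur = T_cur, T_next
    return acc


def characteristic_embedding(
    psis: Sequence[np.ndarray], t_grid: Sequence[float]
) -> np.ndarray:
    """Characteristic-function embedding from wavelet matrices.

    For each scale's Psi and each t, phi_a(t) = mean_m exp(i t Psi[m, a]);
    the output row for node ``a`` concatenates [Re, Im] over (scale, t) in
    order. All coordinates lie in [-1, 1]; at t = 0 they are exactly (1, 0).
    """
    if not psis:
        raise ValueError("at least one wavelet matrix is required")
    n = psis[0].shape[0]
    blocks = []
    for psi in psis:
        if psi.shape != (n, n):
            raise ValueError("wavelet matrices must share a square shape")
        for t in t_grid:
            phi = np.exp(1j * float(t) * psi).mean(axis=0)
            blocks.append(phi.real)
            blocks.append(phi.imag)
    return np.column_stack(blocks)


def _embed_from_laplacian(
    L: sp.csr_array,
    nodes: list[str],
    network: WeightedPPINetwork,
    config: EmbeddingConfig,
    scales: list[float],
    eig: tuple[np.ndarray, np.ndarray] | None,
) -> NodeEmbeddingSet:
    psis = [
        heat_wavelets(L, s, backend=config.backend,
                      chebyshev_order=config.chebyshev_order, eig=eig)
        for s in scales
    ]
    vectors = characteristic_embedding(psis, config.t_grid)
    if vectors.shape[1] != config.n_dims:
        raise ValueError(
            f"embedding dimension mismatch: produced {vectors.shape[1]}, "
            f"config specifies {config.n_dims}"
        )
    edge_sig = ";".join(
        f"{u}|{v}|{w:.12g}"
        for (u, v), w in sorted(
            (tuple(sorted((a, b))), d["weight"])
            for a, b, d in network.graph.edges(data=True)
        )
    )
    scale_sig = ",".join(f"{s:.12g}" for s in scales)
    extra = hashlib.sha256(f"{edge_sig}#{scale_sig}".encode()).hexdigest()
    return NodeEmbeddingSet(
        node_ids=nodes,
        vectors=vectors,
        condition_label=network.condition_label,
        fingerprint=config.fingerprint(extra=extra),
    )


def embed_network(
    network: WeightedPPINetwork, config: EmbeddingConfig = EmbeddingConfig()
) -> NodeEmbeddingSet:
    """Full embedding of one weighted network under a config.

    Deterministic: rerunning on the same network yields bit-identical
    vectors; permuting node labels permutes rows identically. When
    ``config.scales`` is None, diffusion scales are auto-selected from this
    network's own spectrum; to compare embeddings across two networks use
    :func:`embed_pair`, which shares one scale set across the pair.
    """
    L, nodes = build_laplacian(network, normalized=config.normalized_laplacian)
    eig = None
    eigenvalues = None
    if config.backend == "exact":
        eig = _eigendecompose(L)
        eigenvalues = eig[0]
    if config.scales is not None:
        scales = list(config.scales)
    else:
        scales = select_scales(L, n_scales=config.n_scales, eta_pair=config.eta_pair,
                               eigenvalues=eigenvalues)
    return _embed_from_laplacian(L, nodes, network, config, scales, eig)


def embed_pair(
    net_a: WeightedPPINetwork,
    net_b: WeightedPPINetwork,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> tuple[NodeEmbeddingSet, NodeEmbeddingSet]:
    """Embed two same-topology networks with one shared set of scales.

    Differential comparisons require identical wavelet parameters on both
    sides: with per-network auto-selection, a weight change that perturbs
    the spectrum would shift every node's scales — and thus every embedding
    — confounding scale selection with genuine network-context change. The
    shared scales come from the symmetric geometric mean of the two
    networks' spectral references sqrt(lambda_2 * lambda_N), so the pair is
    exchangeable (swapping the arguments swaps the outputs exactly).
    Explicit ``config.scales`` are honoured as-is on both sides.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("paired networks must share a node set")
    prepared = []
    for net in (net_a, net_b):
        L, nodes = build_laplacian(net, normalized=config.normalized_laplacian)
        eig = _eigendecompose(L) if config.backend == "exact" else None
        prepared.append((L, nodes, eig))
    if config.scales is not None:
        scales = list(config.scales)
    else:
        extremes = [
            _spectral_extremes(
                L,
                sp.csgraph.connected_components(L, directed=False, return_labels=False),
                eigenvalues=eig[0] if eig is not None else None,
            )
            for L, _, eig in prepared
        ]
        lam2 = float(np.sqrt(extremes[0][0] * extremes[1][0]))
        lam_max = float(np.sqrt(extremes[0][1] * extremes[1][1]))
        ref = np.sqrt(lam2 * lam_max)
        eta_max, eta_min = config.eta_pair
        s_min, s_max = -np.log(eta_max) / ref, -np.log(eta_min) / ref
        if config.n_scales == 1:
            scales = [float(np.sqrt(s_min * s_max))]
        else:
            scales = list(np.geomspace(s_min, s_max, config.n_scales))
    return tuple(
        _embed_from_laplacian(L, nodes, net, config, scales, eig)
        for (L, nodes, eig), net in zip(prepared, (net_a, net_b))
    )
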