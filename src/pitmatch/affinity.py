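"""Gaussian-kernel affinities between pairs of sulcal graphs.

Node affinities compare the 3D pit coordinates through
``exp(-gamma_v * ||a - a'||^2)`` and edge affinities compare arc lengths
through ``exp(-gamma_e * (l - l')^2)``.  The bandwidths are set by the
median heuristic: the inverse of the median squared attribute distance
pooled over all cross-graph pairs.  Rows and columns belonging to dummy
(padding) nodes are zeroed so that the matching objective is independent
of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GraphPopulation, SulcalGraph


@dataclass
class KernelBandwidths:
    gamma_v: float
    gamma_e: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma_v) and self.gamma_v > 0):
            raise ValueError("gamma_v must be positive and finite")
        if not (np.isfinite(self.gamma_e) and self.gamma_e > 0):
            raise ValueError("gamma_e must be positive and finite")


@dataclass
class PairAffinity:
    """Affinity structure of one graph pair (i, j).

    node_affinity : (n_max, n_max) node kernel, 0 on dummy rows/columns.
    edges_i, edges_j : edge lists of the two graphs (real edges only).
    edge_kernel : (e_i, e_j) kernel between every pair of real edges.
    """

    node_affinity: np.ndarray
    edges_i: list[tuple[int, int]]
    edges_j: list[tuple[int, int]]
    edge_kernel: np.ndarray


def _pooled_median(values: np.ndarray) -> float:
    return float(np.median(values))


def estimate_bandwidths(
    pop: GraphPopulation,
    max_pairs: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> KernelBandwidths:
    """Median-heuristic bandwidths pooled over all cross-graph pairs.

    gamma_v is the inverse of the median squared Euclidean distance between
    node coordinates of different graphs (dummies excluded); gamma_e the
    analogue over squared differences of edge arc lengths.  When the number
    of cross pairs exceeds ``max_pairs`` the median is estimated on a random
    subsample.  A zero median (all attributes identical) falls back to
    gamma = 1 with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    coords = [g.coords[~g.dummy] for g in pop]
    lengths = [np.fromiter(g.edge_lengths.values(), float) for g in pop]
    N = len(pop)

    node_sq: list[np.ndarray] = []
    edge_sq: list[np.ndarray] = []
    n_node_pairs = sum(
        len(coords[i]) * len(coords[j]) for i in range(N) for j in range(i + 1, N)
    )
    thin = max(1.0, n_node_pairs / max_pairs)
    for i in range(N):
        for j in range(i + 1, N):
            if thin > 1.0 and rng.random() > 1.0 / thin:
                continue
            d = coords[i][:, None, :] - coords[j][None, :, :]
            node_sq.append((d**2).sum(-1).ravel())
            if len(lengths[i]) and len(lengths[j]):
                e = lengths[i][:, None] - lengths[j][None, :]
                edge_sq.append((e**2).ravel())
    if not node_sq or not edge_sq:
        raise ValueError("need at least 2 graphs with nodes and edges")

    med_v = _pooled_median(np.concatenate(node_sq))
    med_e = _pooled_median(np.concatenate(edge_sq))
    if med_v <= 0:
        warnings.warn("zero median node distance; falling back to gamma_v = 1")
        med_v = 1.0
    if med_e <= 0:
        warnings.warn("zero median edge distance; falling back to gamma_e = 1")
        med_e = 1.0
    return KernelBandwidths(gamma_v=1.0 / med_v, gamma_e=1.0 / med_e)


def pair_affinity(
    g_i: SulcalGraph, g_j: SulcalGraph, bw: KernelBandwidths
) -> PairAffinity:
    """Gaussian node and edge kernels for one (padded) graph pair."""
    d = g_i.coords[:, None, :] - g_j.coords[None, :, :]
    psi = np.exp(-bw.gamma_v * (d**2).sum(-1))
    psi[g_i.dummy, :] = 0.0
    psi[:, g_j.dummy] = 0.0

    li = np.array([g_i.edge_lengths[e] for e in g_i.edges])
    lj = np.array([g_j.edge_lengths[e] for e in g_j.edges])
    if len(li) and len(lj):
        ke = np.exp(-bw.gamma_e * (li[:, None] - lj[None, :]) ** 2)
    else:
        ke = np.zeros((len(li), len(lj)))
    return PairAffinity(psi, list(g_i.edges), list(g_j.edges), ke)
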