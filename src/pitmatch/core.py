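"""Core domain types for populations of sulcal graphs.

A *sulcal graph* represents the folding pattern of one cortical hemisphere:
one node per sulcal basin (carrying the 3D coordinates of its sulcal pit on
a common unit sphere), and one edge per pair of spatially adjacent basins
(carrying the great-circle arc length between the two pits, in radians).

A population of such graphs is matched jointly; pairwise matchings are
stored as {0,1} assignment matrices and aggregated into a block "bulk"
matrix whose (i, j) block maps nodes of graph i onto nodes of graph j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel reference identity for simulated nodes with no true counterpart.
OUTLIER = -1
#: Sentinel cluster label for nodes left unlabeled by a partial matching.
UNLABELED = -1

_UNIT_TOL = 1e-9


class InvalidCoordinateError(ValueError):
    """Raised when a coordinate expected on the unit sphere is not unit-norm."""


def geodesic_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Great-circle distance (radians) between two unit vectors.

    Parameters
    ----------
    p, q : array-like, shape (3,)
        Cartesian coordinates on the unit sphere.

    Returns
    -------
    float in [0, pi].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for v in (p, q):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise InvalidCoordinateError(f"coordinate {v} is not unit-norm")
    return float(np.arccos(np.clip(np.dot(p, q), -1.0, 1.0)))


def geodesic_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances for an (n, 3) array of unit vectors."""
    g = np.clip(coords @ coords.T, -1.0, 1.0)
    return np.arccos(g)


@dataclass
class SulcalGraph:
    """Undirected attributed graph of sulcal basins.

    Attributes
    ----------
    coords : ndarray, shape (n, 3)
        Unit-sphere pit coordinates, one row per node.  Dummy nodes carry
        the placeholder (0, 0, 0), exempt from the unit-norm invariant.
    edges : list of (int, int)
        Unordered node-index pairs, stored with i < j.
    edge_lengths : dict
        Map (i, j) -> arc length in radians.
    dummy : ndarray of bool, shape (n,)
        True for padding nodes added so all graphs share the same size.
    node_attrs : dict
        Optional extra scalar attributes per node (e.g. basin depth),
        each an ndarray of shape (n,).
    """

    coords: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)
    edge_lengths: dict[tuple[int, int], float] = field(default_factory=dict)
    dummy: np.ndarray | None = None
    node_attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.dummy is None:
            self.dummy = np.zeros(len(self.coords), dtype=bool)
        else:
            self.dummy = np.asarray(self.dummy, dtype=bool)
        self.edges = [tuple(sorted(e)) for e in self.edges]

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_real(self) -> int:
        return int((~self.dummy).sum())

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        n = self.n_nodes
        real = ~self.dummy
        norms = np.linalg.norm(self.coords[real], axis=1)
        if len(norms) and np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidCoordinateError("non-dummy coordinates must be unit-norm")
        for (i, j) in self.edges:
            if i == j:
                raise ValueError("self-loop")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge index out of range")
            if self.dummy[i] or self.dummy[j]:
                raise ValueError("dummy nodes must be isolated")
            length = self.edge_lengths[(i, j)]
            if not (0.0 <= length <= np.pi + _UNIT_TOL):
                raise ValueError("edge length outside [0, pi]")


def weighted_adjacency(g: SulcalGraph) -> np.ndarray:
    """Symmetric adjacency matrix with arc lengths as edge weights.

    Entry (i, j) is the stored edge length if the edge exists, 0 otherwise;
    the diagonal is zero.
    """
    n = g.n_nodes
    A = np.zeros((n, n))
    for (i, j), w in g.edge_lengths.items():
        A[i, j] = w
        A[j, i] = w
    return A


@dataclass
class GraphPopulation:
    """Ordered collection of sulcal graphs to be matched jointly."""

    graphs: list[SulcalGraph]

    def __post_init__(self) -> None:
        if len(self.graphs) < 2:
            raise ValueError("a population needs at least 2 graphs")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, q: int) -> SulcalGraph:
        return self.graphs[q]

    @property
    def n_max(self) -> int:
        return max(g.n_nodes for g in self.graphs)

    @property
    def sizes(self) -> list[int]:
        return [g.n_nodes for g in self.graphs]


def pad_population(pop: GraphPopulation) -> GraphPopulation:
    """Equalize graph sizes by appending isolated dummy nodes.

    Dummy nodes carry the placeholder coordinate (0, 0, 0), are flagged in
    ``dummy`` and never receive edges; original node indices are unchanged.
    """
    n_max = pop.n_max
    padded = []
    for g in pop:
        k = n_max - g.n_nodes
        if k == 0:
            padded.append(g)
            continue
        coords = np.vstack([g.coords, np.zeros((k, 3))])
        dummy = np.concatenate([g.dummy, np.ones(k, dtype=bool)])
        attrs = {
            name: np.concatenate([a, np.full(k, np.nan)])
            for name, a in g.node_attrs.items()
        }
        padded.append(
            SulcalGraph(coords, list(g.edges), dict(g.edge_lengths), dummy, attrs)
        )
    return GraphPopulation(padded)


class BulkAssignment:
    """Block matrix of all pairwise node assignments of a population.

    The full matrix has shape (N * n_max, N * n_max); block (i, j) is the
    assignment of graph i's nodes onto graph j's nodes.  Diagonal blocks are
    identity and block (j, i) is the transpose of block (i, j).
    """

    def __init__(self, matrix: np.ndarray, n_max: int):
        matrix = np.asarray(matrix, dtype=float)
        m = matrix.shape[0]
        if matrix.shape != (m, m) or m % n_max:
            raise ValueError("bulk matrix must be square with size N * n_max")
        self.matrix = matrix
        self.n_max = n_max
        self.n_graphs = m // n_max

    def block(self, i: int, j: int) -> np.ndarray:
        n = self.n_max
        return self.matrix[i * n:(i + 1) * n, j * n:(j + 1) * n]

    def set_block(self, i: int, j: int, X: np.ndarray) -> None:
        n = self.n_max
        if X.shape != (n, n):
            raise ValueError("block shape mismatch")
        self.matrix[i * n:(i + 1) * n, j * n:(j + 1) * n] = X

    def copy(self) -> "BulkAssignment":
        return BulkAssignment(self.matrix.copy(), self.n_max)

    def validate(self, binary: bool = True) -> None:
        n, N = self.n_max, self.n_graphs
        for i in range(N):
            if not np.array_equal(self.block(i, i), np.eye(n)):
                raise ValueError(f"diagonal block {i} is not identity")
            for j in range(i + 1, N):
                X = self.block(i, j)
                if not np.allclose(self.block(j, i), X.T):
                    raise ValueError(f"block ({j},{i}) is not the transpose of ({i},{j})")
                if binary:
                    if not np.isin(X, (0.0, 1.0)).all():
                        raise ValueError("non-binary entries")
                    if (X.sum(0) > 1).any() or (X.sum(1) > 1).any():
                        raise ValueError("row/column sums exceed 1")


def bulk_from_pairs(
    pairs: dict[tuple[int, int], np.ndarray], n_graphs: int, n_max: int
) -> BulkAssignment:
    """Assemble pairwise assignment matrices into a bulk matrix.

    ``pairs`` must provide the (i, j) assignment for every i < j; diagonal
    blocks are set to identity and lower blocks to the transposes.
    """
    m = n_graphs * n_max
    bulk = BulkAssignment(np.zeros((m, m)), n_max)
    for i in range(n_graphs):
        bulk.set_block(i, i, np.eye(n_max))
        for j in range(i + 1, n_graphs):
            X = np.asarray(pairs[(i, j)], dtype=float)
            if X.shape != (n_max, n_max):
                raise ValueError(f"assignment ({i},{j}) has shape {X.shape}")
            bulk.set_block(i, j, X)
            bulk.set_block(j, i, X.T)
    return bulk


def bulk_from_ground_truth(
    ground_truth: list[np.ndarray], pop: GraphPopulation
) -> BulkAssignment:
    """Bulk matrix of the true correspondences of a simulated population.

    Two real nodes are matched iff they share the same (non-outlier)
    reference identity; the result is cycle-consistent by construction.
    """
    n_max = pop.n_max
    N = len(pop)
    pairs = {}
    for i in range(N):
        for j in range(i + 1, N):
            X = np.zeros((n_max, n_max))
            gi, gj = ground_truth[i], ground_truth[j]
            idx_j = {ref: v for v, ref in enumerate(gj) if ref != OUTLIER}
            for u, ref in enumerate(gi):
                if ref != OUTLIER and ref in idx_j:
                    X[u, idx_j[ref]] = 1.0
            pairs[(i, j)] = X
    return bulk_from_pairs(pairs, N, n_max)
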