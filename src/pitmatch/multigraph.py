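"""Multi-graph synchronization of pairwise matchings.

Pairwise matchings of a population are mutually inconsistent in general:
composing the matching i -> j with j -> k need not agree with the direct
matching i -> k.  The methods here refine an initial bulk assignment matrix
toward *cycle consistency* (X_ik = X_ij X_jk for all triples):

- ``msync``: spectral permutation synchronization.  The top-d eigenvectors
  of the bulk matrix embed every node into a common universe; each graph is
  anchored to a reference graph by Hungarian rounding, and all blocks are
  reconstructed through the reference, so the output is exactly consistent.
- ``matcheig``: rank reduction by truncated eigendecomposition followed by
  independent Hungarian rounding of every pair; consistency is improved but
  not guaranteed.
- ``mals``: low-rank matrix recovery.  Minimizes
  ``-<K - alpha 1, X> + lambda ||X||_*`` over X in [0,1]^{m x m}, where K is
  the bulk node-affinity matrix; the nuclear norm induces consistency and
  the entry-wise threshold t yields a *partial* matching (ambiguous nodes
  stay unmatched).
- ``cao_cst``: composition-based refinement; greedily replaces blocks by
  compositions through intermediate graphs whenever that raises the
  population consistency score, ignoring affinities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse.linalg

from .affinity import KernelBandwidths, pair_affinity
from .core import BulkAssignment, GraphPopulation, bulk_from_pairs
from .pairwise import hungarian


class MALSDivergenceError(RuntimeError):
    """Raised when the mALS objective keeps increasing."""


@dataclass
class MALSConfig:
    """Settings of the low-rank recovery solver.

    alpha weights the sparsity term (raising it prunes weak matches),
    lam weights the nuclear norm (raising it enforces more consistency),
    rank caps the truncated decomposition used inside the singular-value
    shrinkage (None = size of the largest graph), threshold binarizes the
    relaxed solution, rho is the ADMM penalty parameter.
    """

    alpha: float = 0.3
    lam: float = 0.5
    rank: int | None = None
    threshold: float = 0.5
    max_iter: int = 100
    tol: float = 1e-4
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("alpha and lam must be >= 0")


def _top_eig(M: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-d eigenpairs (by |eigenvalue|) of a symmetric matrix."""
    m = M.shape[0]
    if d >= m - 1 or m <= 600:
        w, V = np.linalg.eigh(M)
        order = np.argsort(-np.abs(w))[:d]
        return w[order], V[:, order]
    w, V = scipy.sparse.linalg.eigsh(M, k=d, which="LM")
    order = np.argsort(-np.abs(w))
    return w[order], V[:, order]


def msync(bulk: BulkAssignment, d: int | None = None) -> BulkAssignment:
    """Spectral synchronization anchored to the first graph.

    Eigenvectors of the bulk matrix give each graph a universe embedding
    U_i; X_i1 = Hungarian(U_i U_1^T) maps graph i onto the reference, and
    every block is reconstructed as X_ij = X_i1 X_j1^T.  The output is
    cycle-consistent by construction.
    """
    n, N = bulk.n_max, bulk.n_graphs
    d = n if d is None else d
    if d > n:
        raise ValueError("universe size d cannot exceed n_max")
    _, V = _top_eig(bulk.matrix, d)
    U = [V[i * n:(i + 1) * n] for i in range(N)]
    to_ref = [np.eye(n)]
    for i in range(1, N):
        to_ref.append(hungarian(U[i] @ U[0].T))
    pairs = {
        (i, j): to_ref[i] @ to_ref[j].T
        for i in range(N)
        for j in range(i + 1, N)
    }
    return bulk_from_pairs(pairs, N, n)


def matcheig(bulk: BulkAssignment, d: int | None = None) -> BulkAssignment:
    """Rank-reduce the bulk matrix, then round every pair independently.

    U stacks the top-d eigenvectors scaled by sqrt(|eigenvalue|); block
    (i, j) is Hungarian(U_i U_j^T).  Unlike ``msync`` no reference graph is
    used and cycle consistency is not guaranteed.
    """
    n, N = bulk.n_max, bulk.n_graphs
    d = n if d is None else d
    w, V = _top_eig(bulk.matrix, d)
    U = V * np.sqrt(np.abs(w))
    Ui = [U[i * n:(i + 1) * n] for i in range(N)]
    pairs = {
        (i, j): hungarian(Ui[i] @ Ui[j].T)
        for i in range(N)
        for j in range(i + 1, N)
    }
    return bulk_from_pairs(pairs, N, n)


def node_affinity_bulk(
    pop: GraphPopulation, bandwidths: KernelBandwidths
) -> np.ndarray:
    """Bulk matrix K stacking the node-affinity blocks of every graph pair."""
    n, N = pop.n_max, len(pop)
    K = np.zeros((N * n, N * n))
    for i in range(N):
        for j in range(i, N):
            psi = pair_affinity(pop[i], pop[j], bandwidths).node_affinity
            K[i * n:(i + 1) * n, j * n:(j + 1) * n] = psi
            if j > i:
                K[j * n:(j + 1) * n, i * n:(i + 1) * n] = psi.T
    return K


from numba import njit


@njit(cache=True)
def _capped_simplex_rows(flat: np.ndarray) -> None:
    """In-place projection of each row onto {x >= 0, sum(x) <= 1}.

    Nonnegativity plus the unit budget implies x <= 1, so this is the
    partial-assignment constraint of one row: clip at zero when the budget
    is slack, otherwise the standard sort-based simplex projection.
    """
    n_rows, n = flat.shape
    for r in range(n_rows):
        s = 0.0
        for c in range(n):
            if flat[r, c] < 0.0:
                flat[r, c] = 0.0
            else:
                s += flat[r, c]
        if s <= 1.0:
            continue
        u = np.sort(flat[r])[::-1]
        css = 0.0
        tau = 0.0
        for k in range(n):
            css += u[k]
            t = (css - 1.0) / (k + 1)
            if u[k] - t > 0.0:
                tau = t
            else:
                break
        for c in range(n):
            v = flat[r, c] - tau
            flat[r, c] = v if v > 0.0 else 0.0


@njit(cache=True)
def _dykstra_blocks(blocks: np.ndarray, iters: int) -> None:
    """In-place Dykstra projection of each (n, n) block onto the
    partial-assignment polytope {X >= 0, X 1 <= 1, X^T 1 <= 1}."""
    nb, n, _ = blocks.shape
    for b in range(nb):
        X = blocks[b]
        p = np.zeros((n, n))
        q = np.zeros((n, n))
        for _ in range(iters):
            Y = X + p
            _capped_simplex_rows(Y)
            p = X + p - Y
            Zt = np.ascontiguousarray((Y + q).T)
            _capped_simplex_rows(Zt)
            Z = Zt.T
            q = Y + q - Z
            X = np.ascontiguousarray(Z)
        blocks[b] = X


def _project_capped_rows(V: np.ndarray) -> np.ndarray:
    """Exact projection of each row (last axis) onto {x >= 0, sum(x) <= 1}."""
    out = np.ascontiguousarray(V, dtype=np.float64).copy()
    _capped_simplex_rows(out.reshape(-1, V.shape[-1]))
    return out


def _project_assignment_polytope(
    V: np.ndarray, n: int, N: int, iters: int = 15
) -> np.ndarray:
    """Projection onto per-block partial-assignment constraints.

    Each (n, n) block is projected onto
    {X : X >= 0, X 1 <= 1, X^T 1 <= 1} by Dykstra's algorithm alternating
    exact row and column projections; diagonal blocks are pinned to
    identity.  Without the row/column budgets the relaxation degenerates:
    any group of mutually similar nodes could be matched all-to-all at
    once.  Only upper blocks are projected; lower blocks follow by the
    transpose symmetry of both the input and the constraint set.
    """
    upper = [(i, j) for i in range(N) for j in range(i + 1, N)]
    blocks = np.empty((len(upper), n, n))
    for b, (i, j) in enumerate(upper):
        blocks[b] = V[i * n:(i + 1) * n, j * n:(j + 1) * n]
    _dykstra_blocks(blocks, iters)
    out = np.zeros_like(V)
    eye = np.eye(n)
    for q in range(N):
        out[q * n:(q + 1) * n, q * n:(q + 1) * n] = eye
    for b, (i, j) in enumerate(upper):
        out[i * n:(i + 1) * n, j * n:(j + 1) * n] = blocks[b]
        out[j * n:(j + 1) * n, i * n:(i + 1) * n] = blocks[b].T
    return out


def _svt(S: np.ndarray, thresh: float, rank: int) -> tuple[np.ndarray, float]:
    """Singular-value shrinkage of a symmetric matrix, rank-capped.

    Uses a randomized truncated SVD (deterministically seeded) for large
    matrices.  Returns the shrunk matrix and its nuclear norm.
    """
    m = S.shape[0]
    if m <= 600 or rank >= m - 1:
        w, V = np.linalg.eigh(S)
        order = np.argsort(-np.abs(w))[:rank]
        s = np.sign(w[order]) * np.maximum(np.abs(w[order]) - thresh, 0.0)
        keep = s != 0.0
        Z = (V[:, order][:, keep] * s[keep]) @ V[:, order][:, keep].T
        return Z, float(np.abs(s).sum())
    from sklearn.utils.extmath import randomized_svd

    U, sv, Vt = randomized_svd(S, n_components=rank, n_iter=4, random_state=0)
    s = np.maximum(sv - thresh, 0.0)
    keep = s != 0.0
    Z = (U[:, keep] * s[keep]) @ Vt[keep]
    # restore exact symmetry lost to truncation error
    Z = 0.5 * (Z + Z.T)
    return Z, float(s.sum())


def mals(
    K: np.ndarray,
    init: BulkAssignment,
    cfg: MALSConfig | None = None,
    return_info: bool = False,
):
    """Low-rank recovery of a population-consistent partial matching.

    Minimizes f(X) = -<K - alpha 1, X> + lam ||X||_* over relaxed partial
    assignments (X in [0,1]^{m x m} with per-block row/column sums <= 1) by
    ADMM with the splitting X = Z: the X-update projects onto the
    assignment polytope, the Z-update is a rank-capped singular-value
    shrinkage inducing cycle consistency.  The relaxed solution
    is binarized blockwise: within each block, Hungarian rounding on the
    relaxed values proposes candidate matches and only those whose relaxed
    value exceeds ``threshold`` survive; a row with no surviving entry means
    the node stays unmatched in that pair.
    """
    cfg = cfg or MALSConfig()
    n, N = init.n_max, init.n_graphs
    m = N * n
    if K.shape != (m, m):
        raise ValueError("affinity bulk K has wrong shape")
    rank = min(cfg.rank or n, m)
    C = K - cfg.alpha

    Z = init.matrix.astype(float).copy()
    U = np.zeros((m, m))
    objective = []
    bad = flat = 0
    best_f = np.inf
    for it in range(cfg.max_iter):
        X = _project_assignment_polytope(Z - U + C / cfg.rho, n, N)
        Z, nuc = _svt(X + U, cfg.lam / cfg.rho, rank)
        U += X - Z
        # surrogate objective: linear part at the feasible iterate, nuclear
        # part from the shrinkage step; exact at the X = Z fixed point
        f = -float(np.sum(C * X)) + cfg.lam * nuc
        objective.append(f)
        scale = max(1.0, abs(best_f) if np.isfinite(best_f) else 1.0)
        # divergence = sustained blow-up well beyond the best value seen
        if f > best_f + 0.5 * scale:
            bad += 1
            if bad >= 10:
                raise MALSDivergenceError(
                    f"objective diverged for 10 consecutive iterations "
                    f"(best {best_f:.4g}, last values {objective[-10:]})"
                )
        else:
            bad = 0
        best_f = min(best_f, f)
        if it > 0 and abs(f - objective[-2]) / scale < cfg.tol:
            flat += 1
            if flat >= 5:
                break
        else:
            flat = 0

    relaxed = X
    pairs = {}
    for i in range(N):
        for j in range(i + 1, N):
            block = relaxed[i * n:(i + 1) * n, j * n:(j + 1) * n]
            if block.max() <= cfg.threshold:
                pairs[(i, j)] = np.zeros((n, n))
                continue
            P = hungarian(block)
            pairs[(i, j)] = np.where(block > cfg.threshold, P, 0.0)
    out = bulk_from_pairs(pairs, N, n)
    if return_info:
        return out, {"objective": objective, "iterations": len(objective)}
    return out


def _consistency_residual(blocks, a: int, b: int, q: int) -> float:
    """||X_ab - X_aq X_qb||_F for one (pair, intermediate) term."""
    return float(np.linalg.norm(blocks[a, b] - blocks[a, q] @ blocks[q, b]))


def _affected_terms(i: int, j: int, N: int):
    """All residual terms (a, b, q) whose value depends on block (i, j)."""
    terms = set()
    for q in range(N):
        terms.add((i, j, q))
    for b in range(N):
        if b != i and b != j:
            terms.add((min(i, b), max(i, b), j))   # uses X_ij or X_ji as factor
            terms.add((min(j, b), max(j, b), i))
    return terms


def cao_cst(bulk: BulkAssignment, max_sweeps: int = 10) -> BulkAssignment:
    """Composition-based consistency refinement (affinity-blind variant).

    Sweeps over all pairs (i < j); for each pair, the block X_ij is replaced
    by the composition X_ik X_kj over the intermediate graph k (k = i keeps
    the current block) that minimizes the total cycle-consistency residual
    of the population, i.e. maximizes the average per-graph consistency.
    Stops when a sweep changes nothing.
    """
    n, N = bulk.n_max, bulk.n_graphs
    blocks = {
        (i, j): bulk.block(i, j).copy() for i in range(N) for j in range(N)
    }
    for _ in range(max_sweeps):
        changed = False
        for i in range(N):
            for j in range(i + 1, N):
                terms = _affected_terms(i, j, N)
                current = blocks[i, j]
                best_res = sum(_consistency_residual(blocks, *t) for t in terms)
                best_block = None
                for k in range(N):
                    if k == i or k == j:
                        continue
                    cand = blocks[i, k] @ blocks[k, j]
                    if np.array_equal(cand, current):
                        continue
                    blocks[i, j] = cand
                    blocks[j, i] = cand.T
                    res = sum(_consistency_residual(blocks, *t) for t in terms)
                    if res < best_res - 1e-12:
                        best_res = res
                        best_block = cand
                    blocks[i, j] = current
                    blocks[j, i] = current.T
                if best_block is not None:
                    blocks[i, j] = best_block
                    blocks[j, i] = best_block.T
                    changed = True
        if not changed:
            break
    pairs = {(i, j): blocks[i, j] for i in range(N) for j in range(i + 1, N)}
    return bulk_from_pairs(pairs, N, n)


METHODS = ("msync", "matcheig", "mals", "cao")


def run_method(
    name: str,
    pop: GraphPopulation,
    bulk: BulkAssignment,
    bandwidths: KernelBandwidths | None = None,
    config: dict | MALSConfig | None = None,
) -> tuple[BulkAssignment, dict]:
    """Dispatch a synchronization method by name.

    Returns the refined bulk matrix together with a metadata record echoing
    the method name and configuration, for provenance.
    """
    if name not in METHODS:
        raise ValueError(f"unknown method '{name}'; expected one of {METHODS}")
    meta: dict = {"method": name}
    if name == "msync":
        d = (config or {}).get("rank") if isinstance(config, dict) else None
        meta["rank"] = d or bulk.n_max
        return msync(bulk, d), meta
    if name == "matcheig":
        d = (config or {}).get("rank") if isinstance(config, dict) else None
        meta["rank"] = d or bulk.n_max
        return matcheig(bulk, d), meta
    if name == "cao":
        sweeps = (config or {}).get("max_sweeps", 10) if isinstance(config, dict) else 10
        meta["max_sweeps"] = sweeps
        return cao_cst(bulk, sweeps), meta
    # mals
    if bandwidths is None:
        raise ValueError("mals needs kernel bandwidths to build the affinity bulk")
    mcfg = config if isinstance(config, MALSConfig) else MALSConfig(**(config or {}))
    meta["config"] = asdict(mcfg)
    K = node_affinity_bulk(pop, bandwidths)
    out, info = mals(K, bulk, mcfg, return_info=True)
    meta["iterations"] = info["iterations"]
    return out, meta
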