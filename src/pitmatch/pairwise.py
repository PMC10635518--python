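"""Pairwise graph matching as a quadratic assignment problem.

The matching of two attributed graphs maximizes

    J(X) = <Psi, X> + sum_{(a,b) in E_i} sum_{(c,d) in E_j}
                      K_E[(a,b),(c,d)] X[a,c] X[b,d]

over permutation matrices X, where Psi is the node-affinity kernel and K_E
the edge-affinity kernel (both orientations of each undirected edge are
counted).  The program is relaxed to doubly-stochastic matrices and solved
by Frank-Wolfe ascent: at each step the objective is linearized, the linear
assignment subproblem is solved exactly by the Hungarian algorithm, and an
exact line search is taken along the resulting segment.  The final iterate
is projected back to a permutation with one more Hungarian step.

Solving all graph pairs of a population yields the initialization bulk
matrix consumed by every multi-graph synchronization method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .affinity import KernelBandwidths, PairAffinity, pair_affinity
from .core import BulkAssignment, GraphPopulation, bulk_from_pairs


@dataclass
class FWConfig:
    """Frank-Wolfe solver settings."""

    max_iter: int = 100
    tol: float = 1e-6
    init: str = "barycenter"   # barycenter | identity | random
    restarts: int = 8          # extra inits (identity + seeded random); best kept
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.init not in ("barycenter", "identity", "random"):
            raise ValueError(f"unknown init '{self.init}'")


def hungarian(profit: np.ndarray) -> np.ndarray:
    """Permutation matrix maximizing the total profit.

    Solved exactly by the Hungarian algorithm (linear sum assignment);
    the solver is deterministic, so ties are broken reproducibly.
    """
    profit = np.asarray(profit, dtype=float)
    if not np.isfinite(profit).all():
        raise ValueError("profit matrix must be finite")
    rows, cols = linear_sum_assignment(profit, maximize=True)
    P = np.zeros_like(profit)
    P[rows, cols] = 1.0
    return P


class _QuadraticForm:
    """Directed-edge representation of the edge-kernel quadratic term."""

    def __init__(self, aff: PairAffinity, n: int):
        ei = np.array(aff.edges_i, dtype=int).reshape(-1, 2)
        ej = np.array(aff.edges_j, dtype=int).reshape(-1, 2)
        # both orientations of every undirected edge
        self.hi = np.concatenate([ei[:, 0], ei[:, 1]])
        self.ti = np.concatenate([ei[:, 1], ei[:, 0]])
        self.hj = np.concatenate([ej[:, 0], ej[:, 1]])
        self.tj = np.concatenate([ej[:, 1], ej[:, 0]])
        self.K = np.tile(aff.edge_kernel, (2, 2))
        self.n = n
        self.empty = self.K.size == 0

    def value(self, X: np.ndarray, Y: np.ndarray | None = None) -> float:
        """Bilinear form B(X, Y) = sum K_ef X[h_e, h_f] Y[t_e, t_f]; Q(X) = B(X, X)."""
        if self.empty:
            return 0.0
        if Y is None:
            Y = X
        return float(
            np.sum(self.K * X[np.ix_(self.hi, self.hj)] * Y[np.ix_(self.ti, self.tj)])
        )

    def grad_half(self, X: np.ndarray) -> np.ndarray:
        """S(X) with grad Q(X) = 2 S(X)."""
        S = np.zeros((self.n, self.n))
        if self.empty:
            return S
        W = self.K * X[np.ix_(self.ti, self.tj)]
        tmp = np.zeros((self.n, len(self.hj)))
        np.add.at(tmp, self.hi, W)
        np.add.at(S.T, self.hj, tmp.T)
        return S


def _two_opt(P: np.ndarray, psi: np.ndarray, quad: _QuadraticForm) -> np.ndarray:
    """Transposition local search on a permutation matrix.

    Repeatedly applies image swaps that increase the objective until no
    improving swap exists.  Cheap because only the edges incident to the
    two swapped nodes change contribution.
    """
    n = P.shape[0]
    perm = np.argmax(P, axis=1)

    if quad.empty:
        incident = [[] for _ in range(n)]
        j_index = {}
    else:
        incident = [[] for _ in range(n)]
        for e, (a, b) in enumerate(zip(quad.hi, quad.ti)):
            incident[a].append(e)
            incident[b].append(e)
        j_index = {(a, b): f for f, (a, b) in enumerate(zip(quad.hj, quad.tj))}

    def edge_score(e: int, pm: np.ndarray) -> float:
        f = j_index.get((pm[quad.hi[e]], pm[quad.ti[e]]))
        return quad.K[e, f] if f is not None else 0.0

    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        for u1 in range(n - 1):
            for u2 in range(u1 + 1, n):
                delta = (
                    psi[u1, perm[u2]] + psi[u2, perm[u1]]
                    - psi[u1, perm[u1]] - psi[u2, perm[u2]]
                )
                affected = set(incident[u1]) | set(incident[u2])
                if affected:
                    new_perm = perm.copy()
                    new_perm[u1], new_perm[u2] = perm[u2], perm[u1]
                    for e in affected:
                        delta += edge_score(e, new_perm) - edge_score(e, perm)
                if delta > 1e-12:
                    perm[u1], perm[u2] = perm[u2], perm[u1]
                    improved = True
    Q = np.zeros_like(P)
    Q[np.arange(n), perm] = 1.0
    return Q


def qap_objective(X: np.ndarray, aff: PairAffinity) -> float:
    """Value of the matching objective at a (relaxed) assignment X."""
    q = _QuadraticForm(aff, X.shape[0])
    return float(np.sum(aff.node_affinity * X)) + q.value(X)


def _random_doubly_stochastic(n: int, rng: np.random.Generator) -> np.ndarray:
    X = rng.random((n, n))
    for _ in range(20):   # Sinkhorn rounds toward doubly-stochastic
        X /= X.sum(1, keepdims=True)
        X /= X.sum(0, keepdims=True)
    return X


def _initial_iterates(n: int, cfg: FWConfig) -> list[np.ndarray]:
    """Multi-start schedule: requested init first, then the alternatives."""
    named = {
        "barycenter": lambda: np.full((n, n), 1.0 / n),
        "identity": lambda: np.eye(n),
    }
    rng = np.random.default_rng(cfg.seed)
    inits = []
    if cfg.init in named:
        inits.append(named[cfg.init]())
    else:
        inits.append(_random_doubly_stochastic(n, rng))
    for name, make in named.items():
        if len(inits) >= cfg.restarts:
            break
        if name != cfg.init:
            inits.append(make())
    while len(inits) < cfg.restarts:
        inits.append(_random_doubly_stochastic(n, rng))
        if len(inits) < cfg.restarts:
            inits.append(np.eye(n)[rng.permutation(n)])
    return inits


def solve_pair(
    aff: PairAffinity, cfg: FWConfig | None = None, return_info: bool = False
):
    """Frank-Wolfe ascent on the relaxed QAP, rounded to a permutation.

    The ascent is restarted from ``cfg.restarts`` initial points and the
    rounded permutation with the best objective is kept (the relaxation is
    non-convex, so single starts can stall in local optima).  Returns the
    permutation matrix (and, optionally, a convergence record with the
    objective trace of the winning start and a ``converged`` flag).  The
    relaxed objective is non-decreasing across iterations by construction
    of the exact line search.
    """
    cfg = cfg or FWConfig()
    n = aff.node_affinity.shape[0]
    quad = _QuadraticForm(aff, n)
    psi = aff.node_affinity

    best = None
    for X0 in _initial_iterates(n, cfg):
        result = _solve_from(X0, psi, quad, cfg)
        if best is None or result[1]["objective"] > best[1]["objective"]:
            best = result
    P, info = best
    if return_info:
        return P, info
    return P


def _solve_from(X: np.ndarray, psi: np.ndarray, quad: _QuadraticForm, cfg: FWConfig):
    obj = float(np.sum(psi * X)) + quad.value(X)
    trace = [obj]
    converged = False
    n = X.shape[0]
    for _ in range(cfg.max_iter):
        grad = psi + 2.0 * quad.grad_half(X)
        D = hungarian(grad)
        delta = D - X
        b = float(np.sum(grad * delta))
        if b <= 1e-12:
            converged = True
            break
        a = quad.value(delta)
        if a < 0:
            eta = min(1.0, -b / (2.0 * a))
        else:
            eta = 1.0
        X = X + eta * delta
        new_obj = float(np.sum(psi * X)) + quad.value(X)
        assert new_obj >= obj - 1e-9 * max(1.0, abs(obj)), "objective decreased"
        rel = abs(new_obj - obj) / max(1.0, abs(obj))
        obj = new_obj
        trace.append(obj)
        if rel < cfg.tol:
            converged = True
            break

    P = _two_opt(hungarian(X), psi, quad)
    final_obj = float(np.sum(psi * P)) + quad.value(P)
    return P, {"converged": converged, "objective": final_obj, "trace": trace}


def all_pairs(
    pop: GraphPopulation,
    bandwidths: KernelBandwidths,
    cfg: FWConfig | None = None,
) -> BulkAssignment:
    """Solve every pair (i < j) of a padded population and assemble the bulk.

    Pairs are independent, so results do not depend on execution order; the
    lower-triangular blocks are the transposes of the solved upper blocks.
    """
    cfg = cfg or FWConfig()
    n_max = pop.n_max
    if any(g.n_nodes != n_max for g in pop):
        raise ValueError("population must be padded before matching")
    pairs = {}
    for i, j in itertools.combinations(range(len(pop)), 2):
        aff = pair_affinity(pop[i], pop[j], bandwidths)
        pairs[(i, j)] = solve_pair(aff, cfg)
    return bulk_from_pairs(pairs, len(pop), n_max)
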