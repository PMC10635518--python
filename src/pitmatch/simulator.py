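"""Simulator for populations of artificial sulcal graphs.

Real sulcal graphs have no ground-truth correspondence, so benchmarking a
matching method requires synthetic populations in which the true matching
is known by construction.  The generator proceeds in two steps:

1. Draw a *reference* configuration of ``n_ref`` points on the unit sphere:
   many independent uniform configurations are sampled and the one with the
   largest minimum pairwise geodesic distance is kept, emulating the minimum
   spacing between real sulcal pits.
2. For each of the ``N`` subjects, perturb every reference node with a
   von Mises-Fisher draw (concentration ``kappa``, larger = less noise),
   suppress ``n_s`` perturbed nodes and add ``n_o`` uniformly-placed outlier
   nodes, with both counts drawn from a beta-binomial distribution of mean
   ``mu_pert`` and SD ``sigma_pert``; finally connect the surviving points
   by the edges of their 3D convex hull (a triangulation of the sphere) and
   remove a fraction ``p`` of those edges.

Every surviving perturbed node remembers which reference node it came from;
outliers carry the sentinel identity ``OUTLIER``.  This mapping is the
ground truth against which matchings are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.stats import vonmises_fisher

from .core import (
    OUTLIER,
    GraphPopulation,
    SulcalGraph,
    geodesic_distance_matrix,
)


class SimulationError(RuntimeError):
    """Raised when a perturbation or hull step cannot be completed."""


class ParameterizationError(ValueError):
    """Raised when requested beta-binomial moments are infeasible."""


@dataclass
class SimulationConfig:
    """All tunables of the population generator.

    Defaults reproduce the benchmark setting: ``n_ref`` matches the average
    real graph size, ``mu_pert``/``sigma_pert``/``p`` were chosen so that the
    simulated node-count and degree distributions track real populations.
    """

    n_graphs: int = 137
    n_ref: int = 88
    kappa: float = 200.0
    mu_pert: float = 12.0
    sigma_pert: float = 4.0
    p: float = 0.10
    trials: int = 10000
    nu: int | None = None          # beta-binomial support; default 5 * mu_pert
    seed: int = 0
    attach_depth: bool = True      # synthetic per-node depth attribute (mm)
    depth_mean: float = 10.0
    depth_sd: float = 3.0
    depth_noise: float = 1.0

    def __post_init__(self) -> None:
        if self.n_graphs < 2:
            raise ValueError("n_graphs must be >= 2")
        if self.n_ref < 4:
            raise ValueError("n_ref must be >= 4 (convex hull needs 4 points)")
        if not (0.0 <= self.p < 1.0):
            raise ValueError("p must be in [0, 1)")
        if self.mu_pert < 0:
            raise ValueError("mu_pert must be >= 0")
        if self.nu is None:
            self.nu = int(round(5 * self.mu_pert)) if self.mu_pert > 0 else 0


@dataclass
class BetaBinomialParams:
    """Beta-binomial B(nu, alpha, beta) in its shape parameterization."""

    nu: int
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.nu * self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        a, b, n = self.alpha, self.beta, self.nu
        return n * a * b * (a + b + n) / ((a + b) ** 2 * (a + b + 1))


def sample_uniform_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. points uniform on the unit sphere, as an (n, 3) array.

    Normalized 3D standard Gaussian draws: rotation-invariant, hence exactly
    uniform on the sphere.
    """
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_reference_points(
    n_ref: int, trials: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Best-of-``trials`` uniform configurations by minimum pairwise spacing.

    Returns the configuration maximizing the minimum pairwise geodesic
    distance, together with that minimum (radians).
    """
    if n_ref < 2 or trials < 1:
        raise ValueError("need n_ref >= 2 and trials >= 1")
    best: np.ndarray | None = None
    best_min = -1.0
    chunk = max(1, min(trials, 20_000_000 // (n_ref * n_ref) or 1))
    done = 0
    while done < trials:
        b = min(chunk, trials - done)
        pts = rng.standard_normal((b, n_ref, 3))
        pts /= np.linalg.norm(pts, axis=2, keepdims=True)
        # max off-diagonal cosine <-> min geodesic distance
        g = np.einsum("bik,bjk->bij", pts, pts)
        idx = np.arange(n_ref)
        g[:, idx, idx] = -1.0
        max_cos = g.max(axis=(1, 2))
        k = int(np.argmax(-max_cos))
        trial_min = float(np.arccos(np.clip(max_cos[k], -1.0, 1.0)))
        if trial_min > best_min:
            best_min = trial_min
            best = pts[k]
        done += b
    assert best is not None
    return best, best_min


def sample_vmf(
    mu: np.ndarray, kappa: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw from the von Mises-Fisher distribution vMF(mu, kappa) on S2.

    kappa = 0 degenerates to the uniform distribution on the sphere.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        out = sample_uniform_sphere(size, rng)
    else:
        out = np.atleast_2d(vonmises_fisher(np.asarray(mu, float), kappa).rvs(size, random_state=rng))
    return out[0] if size == 1 else out


def invert_betabinomial(mu: float, sigma: float, nu: int) -> BetaBinomialParams:
    """Shape parameters (alpha, beta) of B(nu, alpha, beta) with given moments.

    Uses the moment inversion pi = mu/nu, rho = (sigma^2/(nu pi(1-pi)) - 1)/(nu-1),
    s = 1/rho - 1, alpha = pi s, beta = (1-pi) s.  The requested variance must
    exceed the plain binomial variance nu pi(1-pi) (overdispersion), and the
    implied intra-class correlation rho must stay below 1.
    """
    if nu < 2:
        raise ParameterizationError("nu must be >= 2")
    pi = mu / nu
    if not (0.0 < pi < 1.0):
        raise ParameterizationError("mu must lie strictly inside (0, nu)")
    base_var = nu * pi * (1.0 - pi)
    if sigma**2 <= base_var:
        raise ParameterizationError(
            f"sigma^2 = {sigma**2:.4g} must exceed the binomial variance "
            f"{base_var:.4g} for support nu = {nu}"
        )
    rho = (sigma**2 / base_var - 1.0) / (nu - 1.0)
    if rho >= 1.0:
        raise ParameterizationError("requested variance too large for this support")
    s = 1.0 / rho - 1.0
    return BetaBinomialParams(nu=nu, alpha=pi * s, beta=(1.0 - pi) * s)


def sample_betabinomial(
    params: BetaBinomialParams, rng: np.random.Generator, size: int | None = None
) -> int | np.ndarray:
    """Draw counts via p ~ Beta(alpha, beta) then count ~ Binomial(nu, p)."""
    p = rng.beta(params.alpha, params.beta, size=size)
    out = rng.binomial(params.nu, p)
    return int(out) if size is None else out


def perturb_nodes(
    ref_points: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's node set: vMF-perturbed references, suppressions, outliers.

    Returns the (n, 3) coordinates and the per-node ground-truth identity
    array (reference index, or OUTLIER for added nodes).
    """
    n_ref = len(ref_points)
    if cfg.kappa <= 0:
        raise SimulationError("kappa must be > 0 for node perturbation")
    perturbed = np.vstack([sample_vmf(mu, cfg.kappa, rng) for mu in ref_points])
    identities = np.arange(n_ref)

    if cfg.mu_pert > 0:
        params = invert_betabinomial(cfg.mu_pert, cfg.sigma_pert, cfg.nu)
        n_o = sample_betabinomial(params, rng)
        n_s = sample_betabinomial(params, rng)
        for _ in range(100):
            if n_s < n_ref:
                break
            n_s = sample_betabinomial(params, rng)
        else:
            raise SimulationError("could not draw n_s < number of perturbed nodes")
    else:
        n_o = n_s = 0

    if n_s:
        drop = rng.choice(n_ref, size=n_s, replace=False)
        keep = np.setdiff1d(np.arange(n_ref), drop)
        perturbed = perturbed[keep]
        identities = identities[keep]
    if n_o:
        outliers = sample_uniform_sphere(n_o, rng)
        perturbed = np.vstack([perturbed, outliers])
        identities = np.concatenate([identities, np.full(n_o, OUTLIER)])
    return perturbed, identities


def build_edges(
    coords: np.ndarray, p: float, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], float]]:
    """Convex-hull triangulation edges with a fraction ``p`` removed.

    Points on a sphere in general position yield a full triangulation of
    the sphere, so the hull has exactly 3n - 6 edges; floor(p * |E|) of them
    are then deleted uniformly at random.
    """
    if len(coords) < 4:
        raise SimulationError("convex hull needs at least 4 points")
    try:
        hull = ConvexHull(coords)
    except Exception as exc:  # scipy.spatial.QhullError
        raise SimulationError(f"degenerate convex hull: {exc}") from exc
    edge_set = set()
    for a, b, c in hull.simplices:
        edge_set.add(tuple(sorted((int(a), int(b)))))
        edge_set.add(tuple(sorted((int(b), int(c)))))
        edge_set.add(tuple(sorted((int(a), int(c)))))
    edges = sorted(edge_set)
    n_remove = int(np.floor(p * len(edges)))
    if n_remove:
        drop = set(map(int, rng.choice(len(edges), size=n_remove, replace=False)))
        edges = [e for k, e in enumerate(edges) if k not in drop]
    dist = geodesic_distance_matrix(coords)
    lengths = {(i, j): float(dist[i, j]) for (i, j) in edges}
    return edges, lengths


def generate_population(
    cfg: SimulationConfig,
) -> tuple[GraphPopulation, list[np.ndarray], np.ndarray]:
    """Generate a full population with ground truth.

    One reference configuration is shared by all graphs; each graph gets an
    independent perturbation + edge-construction pass.  Per-graph RNG
    substreams are derived from the seed, so regenerating with a larger
    ``n_graphs`` leaves earlier graphs unchanged.

    Returns
    -------
    (population, ground_truth, reference_points)
        ``ground_truth[q][v]`` is the reference identity of node v of graph
        q, or OUTLIER.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_graphs + 1)
    rng_ref = np.random.default_rng(children[0])
    refs, _ = generate_reference_points(cfg.n_ref, cfg.trials, rng_ref)
    if cfg.attach_depth:
        ref_depth = rng_ref.normal(cfg.depth_mean, cfg.depth_sd, size=cfg.n_ref)

    graphs: list[SulcalGraph] = []
    ground_truth: list[np.ndarray] = []
    for q in range(cfg.n_graphs):
        rng = np.random.default_rng(children[q + 1])
        coords, ids = perturb_nodes(refs, cfg, rng)
        edges, lengths = build_edges(coords, cfg.p, rng)
        attrs = {}
        if cfg.attach_depth:
            depth = np.where(
                ids == OUTLIER,
                rng.normal(cfg.depth_mean, cfg.depth_sd, size=len(ids)),
                ref_depth[np.clip(ids, 0, None)] + rng.normal(0, cfg.depth_noise, len(ids)),
            )
            attrs["depth"] = depth
        graphs.append(SulcalGraph(coords, edges, lengths, node_attrs=attrs))
        ground_truth.append(ids)
    return GraphPopulation(graphs), ground_truth, refs


def population_summary(pop: GraphPopulation) -> dict:
    """Distributional fingerprint of a population, for comparison with real data.

    Reports the node-count distribution across graphs, the pooled node-degree
    distribution, and the pooled edge arc-length distribution.
    """
    sizes = np.array([g.n_real for g in pop])
    degrees = []
    lengths = []
    for g in pop:
        deg = np.zeros(g.n_nodes, dtype=int)
        for (i, j) in g.edges:
            deg[i] += 1
            deg[j] += 1
        degrees.extend(deg[~g.dummy].tolist())
        lengths.extend(g.edge_lengths.values())
    degrees = np.array(degrees)
    lengths = np.array(lengths)
    return {
        "node_count_mean": float(sizes.mean()),
        "node_count_sd": float(sizes.std(ddof=1)),
        "node_counts": sizes,
        "degree_mean": float(degrees.mean()),
        "degrees": degrees,
        "edge_length_mean": float(lengths.mean()),
        "edge_lengths": lengths,
    }
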