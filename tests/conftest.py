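import numpy as np
import pytest

from pitmatch.core import GraphPopulation, SulcalGraph, pad_population
from pitmatch.simulator import SimulationConfig, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_population(seed=3, kappa=1000.0, n_graphs=6, n_ref=12,
                     mu_pert=2.0, sigma_pert=2.0, p=0.1):
    """Small noisy population used across matching tests."""
    cfg = SimulationConfig(
        n_graphs=n_graphs, n_ref=n_ref, kappa=kappa, mu_pert=mu_pert,
        sigma_pert=sigma_pert, p=p, trials=50, seed=seed,
    )
    return generate_population(cfg)


def noiseless_population(seed=3, n_graphs=5, n_ref=12):
    """Outlier-free population with negligible coordinate noise."""
    cfg = SimulationConfig(
        n_graphs=n_graphs, n_ref=n_ref, kappa=1e8, mu_pert=0.0,
        sigma_pert=0.0, p=0.0, trials=50, seed=seed,
    )
    return generate_population(cfg)


@pytest.fixture
def tiny_pop():
    pop, gt, refs = small_population()
    return pad_population(pop), gt


@pytest.fixture
def noiseless_pop():
    pop, gt, refs = noiseless_population()
    return pad_population(pop), gt


def triangle_graph():
    """Three orthogonal unit vectors connected in a triangle."""
    coords = np.eye(3)
    edges = [(0, 1), (0, 2), (1, 2)]
    lengths = {e: np.pi / 2 for e in edges}
    return SulcalGraph(coords, edges, lengths)
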