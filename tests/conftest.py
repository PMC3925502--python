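import numpy as np
import pytest

import drfseg as d


@pytest.fixture(scope="session")
def training_set():
    """Four isolated-nodule training phantoms (the stock training regime)."""
    return d.make_training_set(4, rng_seed=7)


@pytest.fixture(scope="session")
def intensity_model(training_set):
    return d.fit_intensity_model([(v, m) for v, m, _ in training_set])


@pytest.fixture(scope="session")
def trained_results(training_set):
    """Full F-score annealing fit (500 iterations, fixed seed) on the four
    training phantoms; shared because training dominates suite runtime."""
    model = d.NoduleDRF(training_set)
    return model.fit(d.AnnealConfig(iterations=500, rng_seed=1))


@pytest.fixture(scope="session")
def hand_params(intensity_model):
    """Plausible hand-picked parameters: inside-the-nodule bias, penalties on
    the intensity z-score, the out-of-threshold indicator and distance."""
    return d.DrfParams(w=[4.0, -1.0, -6.0, -3.0], v=0.5, model=intensity_model)


def random_ising_energy(rng, shape=(2, 2, 3), unary_sd=3.0, k_max=2.0):
    """A random submodular Ising-type pairwise energy on a small grid."""
    from drfseg.drf import PairwiseEnergy, grid_edges

    n = int(np.prod(shape))
    unary = rng.normal(0, unary_sd, (n, 2))
    edges = grid_edges(shape)
    k = rng.uniform(0, k_max, len(edges))
    pw = np.empty((len(edges), 2, 2))
    pw[:, 0, 0] = pw[:, 1, 1] = -k
    pw[:, 0, 1] = pw[:, 1, 0] = k
    return PairwiseEnergy(unary=unary, edges=edges, pairwise=pw, shape=shape)


def random_general_energy(rng, shape=(2, 2, 3)):
    """A random submodular energy with general (non-Ising) 2x2 tables."""
    from drfseg.drf import PairwiseEnergy, grid_edges

    n = int(np.prod(shape))
    unary = rng.normal(0, 3.0, (n, 2))
    edges = grid_edges(shape)
    E = len(edges)
    A = rng.normal(0, 1, E)
    D = rng.normal(0, 1, E)
    gap = rng.uniform(0, 3, E)  # B + C - A - D = gap >= 0
    B = (A + D) / 2 + gap * rng.uniform(0.3, 1.0, E)
    C = A + D + gap - B
    pw = np.stack([np.stack([A, B], -1), np.stack([C, D], -1)], axis=1)
    return PairwiseEnergy(unary=unary, edges=edges, pairwise=pw, shape=shape)
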