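"""Shared fixtures: simulated screens fitted once per session."""

import numpy as np
import pytest

from emapkit import EMapScreen, InteractionMatrix, SimConfig, simulate_screen


@pytest.fixture(scope="session")
def default_world():
    """Default two-condition screen (120 genes, one planted suppressor)."""
    truth, grids = simulate_screen(SimConfig(), seed=7)
    return truth, grids


@pytest.fixture(scope="session")
def default_results(default_world):
    truth, grids = default_world
    return truth, EMapScreen(grids, truth.loci).fit()


@pytest.fixture(scope="session")
def noisefree_world():
    """Noise-free, uniform-fitness screen: the exact-limit world."""
    cfg = SimConfig(noise_cv=0.0, fitness_sd=0.0)
    truth, grids = simulate_screen(cfg, seed=11, conditions=("control",))
    return truth, grids


@pytest.fixture(scope="session")
def noisefree_results(noisefree_world):
    truth, grids = noisefree_world
    return truth, EMapScreen(grids, truth.loci).fit()


def make_matrix(n, seed=0, genes=None, p_from_null=True):
    """Random symmetric InteractionMatrix for unit tests."""
    rng = np.random.default_rng(seed)
    genes = genes or [f"g{i:03d}" for i in range(n)]
    S = rng.normal(size=(n, n))
    S = (S + S.T) / 2
    m = InteractionMatrix(genes, S)
    if p_from_null:
        from emapkit.scoring import s_pvalues

        if n >= 12:  # empirical null needs 50 finite pairs
            m = s_pvalues(m)
    return m
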