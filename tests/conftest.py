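from __future__ import annotations

import numpy as np
import pytest

from netdissim import InteractionMatrix, SimulationConfig, simulate_dataset


def make_net(network_id: str, weights, plants=None, birds=None) -> InteractionMatrix:
    w = np.asarray(weights, dtype=float)
    plants = plants or tuple(f"p{i}" for i in range(w.shape[0]))
    birds = birds or tuple(f"b{j}" for j in range(w.shape[1]))
    return InteractionMatrix(network_id, tuple(plants), tuple(birds), w)


def random_net(rng: np.random.Generator, network_id: str, pool: int = 8, max_dim: int = 6) -> InteractionMatrix:
    """Random small network drawing species labels from a shared pool so
    pairs of networks share some species."""
    while True:
        nr = int(rng.integers(2, max_dim + 1))
        nc = int(rng.integers(2, max_dim + 1))
        plants = rng.choice(pool, size=nr, replace=False)
        birds = rng.choice(pool, size=nc, replace=False)
        w = rng.integers(0, 3, (nr, nc)) * np.round(rng.random((nr, nc)) * 4 + 0.1, 2)
        if w.sum() > 0 and (w.sum(1) > 0).all() and (w.sum(0) > 0).all():
            return InteractionMatrix(
                network_id,
                tuple(f"p{i}" for i in plants),
                tuple(f"b{j}" for j in birds),
                w,
            )


@pytest.fixture(scope="session")
def small_dataset():
    """Shared synthetic dataset (12 networks) for pipeline-level tests."""
    cfg = SimulationConfig(
        seed=11, n_biomes=2, ecoregions_per_biome=2, sites_per_ecoregion=3,
        n_studies=4,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_dataset():
    """Shared synthetic dataset (60 networks, study defaults)."""
    return simulate_dataset(SimulationConfig(seed=3))
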