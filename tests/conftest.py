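"""Shared fixtures: small-scale simulation batches reused across tests.

The mechanical simulations are the expensive part of the suite, so batches
are session-scoped and deliberately scaled down (small rim margins, few pairs
per condition) relative to the full study conditions; the statistical
assertions that consume them carry tolerances sized accordingly.
"""

import numpy as np
import pytest

from ecmcomm.network import GenerationConfig, generate_network, carve_cell_voids
from ecmcomm.mechanics import ContractionSchedule, run_contraction_simulation
from ecmcomm.pipeline import (
    simulate_pair_batch,
    simulate_single_cells,
    simulate_leader_follower_batch,
)

TEST_MARGIN = 5.0  # cell diameters of rim margin in test-scale simulations
FAST_MARGIN = 3.0  # for checks that need signal presence, not calibrated statistics


@pytest.fixture(scope="session")
def svd_batches():
    """Five communicating pairs per pair distance in {4, 5, 7, 9} (mu=1%, sd=0.5%).

    Distance 9 uses a slightly larger rim margin: there the outer boundary
    would otherwise sit closer to each cell than its partner does.
    """
    batches = {}
    for i, dist in enumerate((4.0, 5.0, 7.0, 9.0)):
        batches[dist] = simulate_pair_batch(
            5,
            pair_distance=dist,
            mu=1.0,
            sigma=0.5,
            base_seed=1000 + 100 * i,
            margin_diameters=6.0 if dist == 9.0 else TEST_MARGIN,
        )
    return batches


@pytest.fixture(scope="session")
def sigma_batches(svd_batches):
    """Pair batches at distance 5 for contraction heterogeneity 0, 0.25, 0.5 %."""
    return {
        0.0: simulate_pair_batch(
            4, pair_distance=5.0, mu=1.0, sigma=0.0, base_seed=2000,
            margin_diameters=TEST_MARGIN,
        ),
        0.25: simulate_pair_batch(
            4, pair_distance=5.0, mu=1.0, sigma=0.25, base_seed=2100,
            margin_diameters=TEST_MARGIN,
        ),
        0.5: svd_batches[5.0],
    }


@pytest.fixture(scope="session")
def leader_batch():
    """Pairs where cell 0 leads and cell 1 copies with one-step lag (alpha=1)."""
    return simulate_leader_follower_batch(
        3, alpha=1.0, pair_distance=4.0, base_seed=2500, margin_diameters=FAST_MARGIN
    )


@pytest.fixture(scope="session")
def passive_batch():
    """Pairs of one contractile and one passive (non-contractile) cell."""
    return simulate_pair_batch(
        3, pair_distance=5.0, mu=1.0, sigma=0.5, base_seed=2700,
        margin_diameters=TEST_MARGIN, passive_second=True,
    )


@pytest.fixture(scope="session")
def single_cell_profiles():
    """Seven single contracting cells, z-density at window distances 0..3."""
    return simulate_single_cells(
        7, base_seed=3000, margin_diameters=8.0, window_distances=np.arange(0.0, 4.0)
    )


@pytest.fixture(scope="session")
def small_pair_traj():
    """One quick 10-step pair contraction for unit-level checks."""
    cfg = GenerationConfig(domain_halfwidth=0.4, rng_seed=42)
    geom = carve_cell_voids(generate_network(cfg), np.array([[-0.16, 0.0], [0.16, 0.0]]))
    sched = ContractionSchedule.heterogeneous(2, mu=1.0, sigma=0.5, n_steps=10, rng_seed=42)
    return run_contraction_simulation(geom, sched)
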