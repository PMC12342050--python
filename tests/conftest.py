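import numpy as np
import pytest

from shsize import (
    SimConfig,
    SingleStepParams,
    make_partition_law,
    simulate_lineage,
    stationary_estimate,
)


@pytest.fixture(scope="session")
def det_law():
    """Deterministic halving (beta = 1/2 with probability one)."""
    return make_partition_law(0.5, 0.0)


@pytest.fixture(scope="session")
def noisy_law():
    return make_partition_law(0.5, 0.1)


@pytest.fixture(scope="session")
def adder_run(det_law):
    """One long adder lineage (mu = k = 1, precise halving), shared by the
    simulation-vs-formula checks."""
    cfg = SimConfig(
        model=SingleStepParams(mu=1.0, k=1.0, alpha=1.0),
        partition=det_law,
        n_cycles=100_000,
        burn_in_cycles=100,
        seed=2024,
    )
    traj, cycles = simulate_lineage(cfg)
    est = stationary_estimate(cfg)
    return cfg, traj, cycles, est


def block_cv2_se(x: np.ndarray, n_blocks: int = 50) -> tuple[float, float]:
    """Sample CV2 of a (possibly autocorrelated) series with a block SE."""
    x = np.asarray(x)
    cv2 = float(np.var(x, ddof=1) / np.mean(x) ** 2)
    blocks = np.array_split(x, n_blocks)
    vals = [np.var(b, ddof=1) / np.mean(b) ** 2 for b in blocks]
    return cv2, float(np.std(vals, ddof=1) / np.sqrt(n_blocks))
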