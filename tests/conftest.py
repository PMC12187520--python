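import numpy as np
import pytest

from ntchrom.genome import GenomeSpec
from ntchrom.pipeline import RunConfig, run_pipeline
from ntchrom.simulate import SimulationConfig, simulate_genome


@pytest.fixture
def small_genome() -> GenomeSpec:
    """Two small chromosomes (50 + 30 bins of 200 bp)."""
    return GenomeSpec(("chrA", "chrB"), (10_000, 6_000), 200)


@pytest.fixture(scope="session")
def default_sim():
    """Default-config simulation (seed 0): (config, genome, genes, truth)."""
    cfg = SimulationConfig(seed=0)
    genome, genes, truth = simulate_genome(cfg)
    return cfg, genome, genes, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run shared by the slower integration tests."""
    return run_pipeline(RunConfig())


def random_states(rng: np.random.Generator, genome: GenomeSpec) -> np.ndarray:
    """Random four-state bin vector with blocky structure."""
    n = genome.total_bins
    out = np.zeros(n, dtype=np.uint8)
    pos = 0
    while pos < n:
        run = int(rng.integers(1, 8))
        out[pos : pos + run] = rng.integers(0, 4)
        pos += run
    return out
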