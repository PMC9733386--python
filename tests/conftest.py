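import numpy as np
import pytest

from asqtl.config import SimulationConfig
from asqtl import simulate, phasing


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_animals=80, n_chromosomes=2, chrom_length=500_000,
        n_snps_per_chrom=150, n_peaks=60, n_exons=60,
        frac_causal_features=0.3, seed=11,
        planted_motifs=[("TGACTCAGT", 30)])


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One simulated study shared across test modules."""
    panel, features, counts, genome, manifest = simulate.simulate_all(small_config)
    return {"panel": panel, "features": features, "counts": counts,
            "genome": genome, "manifest": manifest, "config": small_config}


@pytest.fixture(scope="session")
def small_phase(small_sim):
    return phasing.phase_panel(small_sim["panel"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
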