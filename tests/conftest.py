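import numpy as np
import pytest

from calcifit import AssayDesign, default_truth, simulate_crc


@pytest.fixture(scope="session")
def truth_high_affinity():
    """Reference-compound-like truth: pKB 7.06, log alphabeta -1.87."""
    return default_truth(pKB=7.06, log_alphabeta=-1.87)


@pytest.fixture(scope="session")
def truth_low_affinity():
    """Chemoreactive-compound-like truth: pKB 6.39, log alphabeta -2.38."""
    return default_truth(pKB=6.39, log_alphabeta=-2.38)


@pytest.fixture(scope="session")
def noise_free_surface(truth_high_affinity):
    """Single-experiment noise-free surface on the default plate design."""
    design = AssayDesign(noise_sd_pct_Em=0.0, n_experiments=1, seed=1)
    return simulate_crc(design, truth_high_affinity)


@pytest.fixture(scope="session")
def noisy_surface(truth_high_affinity):
    """Default design (4 experiments, 5% Em noise), fixed seed."""
    return simulate_crc(AssayDesign(seed=11), truth_high_affinity)
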