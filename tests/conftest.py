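import numpy as np
import pytest

from umprofiler.panel_model import reference_panel
from umprofiler.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """44-patient simulated cohort shared by integration tests."""
    cfg = SimConfig(n_patients=44, seed=7)
    variants, snps, clinical, survival, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "variants": variants,
        "snps": snps,
        "clinical": clinical,
        "survival": survival,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
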