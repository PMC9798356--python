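import math

import pytest

from bmiphenet.config import PhecodeSpec, SimulationConfig
from bmiphenet.simulate import simulate_cohort


@pytest.fixture(scope="session")
def cohort20k():
    """Biobank-scale cohort: n=20,000, 250 variants of which 200 causal,
    h2=0.2, no LD, default disease panel. Shared across recovery tests."""
    cfg = SimulationConfig(
        n_individuals=20_000, n_variants=250, n_causal=200, h2_bmi=0.2,
        ld_rho=0.0, seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_ld_cohort():
    """Small cohort with strong block LD (rho=0.9, blocks of 10) for
    clumping and LD-structure tests."""
    cfg = SimulationConfig(
        n_individuals=2_000, n_variants=400, n_causal=50, h2_bmi=0.3,
        ld_rho=0.9, ld_block_size=10, seed=5,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_blocks_cfg():
    """Two planted comorbidity blocks of eight 3-digit codes each, strong
    latent loadings, no BMI effect: the ground truth for network tests."""
    specs = []
    for block, base in [("A", 100), ("B", 200)]:
        for k in range(8):
            specs.append(PhecodeSpec(str(base + k), 0.25, 0.0, block, 1.5))
    return SimulationConfig(
        n_individuals=4_000, n_variants=10, n_causal=1, h2_bmi=0.0,
        phecode_spec=specs, seed=7,
    )
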