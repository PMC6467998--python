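import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from csprs.simulator import (ArchitectureSpec, draw_effects,
                             ld_blocks_from_cohort, rss_sumstats,
                             scale_effects_to_h2, simulate_genotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_cohort():
    """Small genotype cohort shared across read-only tests."""
    return simulate_genotypes(n=600, m=120, n_blocks=4, ld_decay=0.7,
                              maf_range=(0.1, 0.5), seed=42)


@pytest.fixture(scope="session")
def medium_sim():
    """Moderate simulated dataset with reference LD, true effects and
    direct-route summary statistics, for sampler-level tests."""
    rng = np.random.default_rng(99)
    cohort = simulate_genotypes(n=600, m=2000, n_blocks=20, seed=rng)
    blocks = ld_blocks_from_cohort(cohort, rows=np.arange(503))
    spec = ArchitectureSpec(family="point_normal", n_causal=100, h2=0.5)
    beta_raw, _ = draw_effects(spec, 2000, rng)
    beta = scale_effects_to_h2(beta_raw, blocks, 0.5)
    hstats = rss_sumstats(beta, blocks, n=50_000, seed=rng, h2=0.5)
    return {"cohort": cohort, "blocks": blocks, "beta_true": beta,
            "hstats": hstats}
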