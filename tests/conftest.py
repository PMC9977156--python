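import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from lepihox.simulate import SimulationConfig, generate, synthetic_reference_set


@pytest.fixture(scope="session")
def refset():
    """Synthetic three-species homeodomain reference panel over the full
    family catalog."""
    return synthetic_reference_set(seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """A compact Hox-only genome (~1 Mb) with the canonical layout."""
    config = SimulationConfig(
        seed=1,
        intergenic_median_bp=20_000,
        intergenic_sigma=0.6,
        lab_offset_bp=500_000,
        include_nk=False,
        include_prd=False,
        end_margin=100_000,
    )
    return generate(config)


@pytest.fixture(scope="session")
def small_pipeline(small_sim, refset):
    """Scan + classify the small genome once for reuse across tests."""
    from lepihox.classify import classify_all
    from lepihox.scan import find_loci

    loci, hits = find_loci(small_sim.contigs, refset)
    classified = classify_all(loci, refset)
    return small_sim, loci, hits, classified
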