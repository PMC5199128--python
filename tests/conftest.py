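import pytest

from apadiv import pipeline
from apadiv.simulate import SimConfig


@pytest.fixture(scope="session")
def bundle200():
    """Mid-size simulation with planted effects, no 3' READS streams.

    Shared by reference/quantify/divergence tests; treat as read-only.
    """
    cfg = SimConfig(seed=2024, n_genes=200, chrom_length_bp=600_000,
                    cis_effect_fraction=0.2, trans_effect_fraction=0.1,
                    read_depth_per_sample=120_000, background_depth=40_000)
    return pipeline.simulate_all(cfg, with_3reads=False)


@pytest.fixture(scope="session")
def discovery_bundle():
    """Small simulation including 3' READS reads and RNA-Seq background."""
    cfg = SimConfig(seed=7, n_genes=80, chrom_length_bp=250_000,
                    read_depth_per_sample=60_000, background_depth=30_000)
    return pipeline.simulate_all(cfg, with_3reads=True)
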