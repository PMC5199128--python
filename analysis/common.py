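"""Shared configuration for the numbered analysis drivers.

The standing synthetic study: a two-chromosome strain pair at SPRET-like
variant density, 150 genes, planted cis and trans APA effects, and all read
streams.  Every driver reads its inputs from (and writes its outputs to)
``results/`` so the steps can be rerun independently.
"""

import os

from apadiv.simulate import SimConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
SIMDIR = os.path.join(RESULTS, "sim")

STUDY_CONFIG = SimConfig(
    seed=1,
    n_genes=300,
    chrom_length_bp=900_000,
    cis_effect_fraction=0.15,
    trans_effect_fraction=0.05,
    read_depth_per_sample=600_000,
    background_depth=150_000,
)


def rpath(*parts: str) -> str:
    path = os.path.join(RESULTS, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path
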