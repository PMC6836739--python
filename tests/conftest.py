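import numpy as np
import pytest
from hypothesis import settings

from cstss import ChromSizes, SimConfig, StrandedCoverage

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_cov(positions, library_size=None, chrom_len=None, label="test"):
    """Coverage from {(chrom, strand): [pos, ...]} with optional genome."""
    sizes = None
    if chrom_len is not None:
        sizes = ChromSizes()
        for chrom in {c for c, _ in positions}:
            sizes[chrom] = chrom_len
    return StrandedCoverage.from_position_lists(
        positions, library_size, sizes=sizes, label=label)


@pytest.fixture
def small_sim_config():
    """A fast, fully planted mini-genome for plumbing-level tests."""
    return SimConfig(seed=7, n_chroms=2, chrom_len=400_000, n_genes=6,
                     n_enhancers=3, depth_csrna=120_000,
                     depth_input=120_000, depth_rnaseq=120_000)


@pytest.fixture
def sim_dataset(small_sim_config):
    from cstss import (make_annotation, simulate_csrna, simulate_input,
                       simulate_rnaseq)
    cfg = small_sim_config
    genes, truth, sizes = make_annotation(cfg)
    return {
        "cfg": cfg, "genes": genes, "truth": truth, "sizes": sizes,
        "csrna": simulate_csrna(cfg, truth, genes),
        "input": simulate_input(cfg, truth, genes),
        "rnaseq": simulate_rnaseq(cfg, truth, genes),
    }
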