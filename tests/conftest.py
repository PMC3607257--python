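import numpy as np
import pytest

from orcmap.annotation import GeneRecord


def make_genes(layout, chromosome="chr1", start=0, length=1_000, gap=500):
    """Build a sequential gene list from (strand, category) pairs."""
    genes = []
    pos = start
    for k, item in enumerate(layout):
        strand, category = item if isinstance(item, tuple) else (item, "ordinary")
        genes.append(
            GeneRecord(f"g{k}", chromosome, pos, pos + length, strand, category)
        )
        pos += length + gap
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """One small default-condition chromosome with full ground truth."""
    from orcmap import simulate

    cfg = simulate.SimulationConfig(chromosomes={"chr1": 800_000})
    _, genes, truth = simulate.generate_genome(cfg, seed=7)
    return cfg, genes, truth
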