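import numpy as np
import pytest

from skullcap.io import GeneModel, Genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genome(name, gene_specs):
    """Build a Genome from (gene_id, chrom, start, cds) tuples, strand +."""
    genes = [GeneModel(gene_id=g, chromosome=c, start=s, end=s + len(cds),
                       strand="+", cds=cds) for g, c, s, cds in gene_specs]
    return Genome(name, genes)


@pytest.fixture
def tiny_scenario():
    from skullcap.simulate import EvolutionScenario

    return EvolutionScenario(n_chromosomes=1, genes_per_chromosome=20,
                             cds_length_codons=(100, 200), wgd_age=None,
                             speciation_age=6.15e6, seed=7)
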