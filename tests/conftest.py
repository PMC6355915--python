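import numpy as np
import pytest

from polpause.genome_io import CoverageTrack, GeneModel
from polpause.simulate import SimulationConfig, simulate_genes, simulate_chip


@pytest.fixture(scope="session")
def small_genome():
    """60 simulated genes on one contig, fixed seed."""
    return simulate_genes(SimulationConfig(n_genes=60, seed=7))


@pytest.fixture(scope="session")
def chip_control(small_genome):
    return simulate_chip(small_genome, "control")


def make_track(contig, dense, offset=0, label=""):
    return CoverageTrack.from_dense(contig, np.asarray(dense, float),
                                    label=label, offset=offset)


def simple_gene(gene_id="g", contig="chr1", strand="+", start=0, end=10_000,
                blocks=None, tss_list=None):
    if blocks is None:
        blocks = ((start, end),)
    if strand == "+":
        tss, tes = start, end
    else:
        tss, tes = end, start
    return GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                     tss_list=tuple(tss_list) if tss_list else (tss,),
                     tes=tes, exon_blocks=tuple(blocks))
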