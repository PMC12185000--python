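import numpy as np
import pandas as pd
import pytest

from f2map import cross_from_truth
from f2map.genome import GenomeSpec, default_genome
from f2map.simulate import QTL, QTLSpec, simulate_f2, simulate_phenotypes


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def one_chrom_genome():
    """Single 25-Mb chromosome = 100 cM per gamete at 4 cM/Mb."""
    return GenomeSpec(chromosomes=(("Chr1", 25_000_000),), cm_per_mb=4.0)


@pytest.fixture(scope="session")
def qtl_cross(genome):
    """200 F2 individuals with one planted additive QTL (PEV 50%)."""
    truth = simulate_f2(genome, 200, seed=101)
    spec = QTLSpec(qtl=(QTL("Chr1", 24_675_000, float(np.sqrt(2)), 0.0),), residual_sd=1.0)
    pheno = simulate_phenotypes(truth, spec, seed=102).set_index("individual")
    cross = cross_from_truth(truth, genome, phenotypes=pheno)
    cross.truth = truth  # available to recovery tests
    cross.qtl_spec = spec
    return cross


def make_truth(genome, chrom_states):
    """Hand-built TrueF2Genome list from {chrom: [(start, end, state), ...]} dicts."""
    from f2map.simulate import TrueF2Genome

    out = []
    for i, segs in enumerate(chrom_states):
        crossovers = []
        for chrom, seglist in segs.items():
            crossovers.extend((chrom, s[0]) for s in seglist[1:])
        out.append(TrueF2Genome(f"F2_{i:04d}", segs, crossovers))
    return out
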