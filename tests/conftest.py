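import pytest

from tetrasnp.alignment import ContigAlignment, build_contig_alignment
from tetrasnp.discovery import CallerConfig, call_contigs, classify_candidates
from tetrasnp.simulate import SimulationConfig, simulate_dataset

GENOTYPES = ("Chilean", "Wisfal")


def make_contig(contig_id, reads):
    """Build a contig from (read_id, genotype, offset, padded_seq) tuples."""
    return ContigAlignment.from_padded_reads(contig_id, reads)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small dataset under the default (error-bearing) study conditions."""
    config = SimulationConfig(n_loci=20, seed=101)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free dataset used by the exact recovery checks."""
    config = SimulationConfig(n_loci=30, seed=202, sub_error_rate=0.0,
                              homopolymer_indel_rate=0.0)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_contigs(clean_dataset):
    return build_contig_alignment(clean_dataset.reads,
                                  clean_dataset.transcripts)


@pytest.fixture(scope="session")
def clean_snps(clean_contigs):
    snps = call_contigs(clean_contigs, CallerConfig())
    classify_candidates(snps, genotype_order=list(GENOTYPES))
    return snps
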