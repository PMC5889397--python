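import pytest

from adipolnc.model import GenomicInterval, TranscriptModel
from adipolnc.synthetic import SimulationConfig, simulate_gene_models


def make_transcript(tid, chrom, strand, exon_coords, gene_id=None, **kw):
    """Shorthand transcript constructor for tests."""
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    return TranscriptModel(tid, gene_id or tid, exons, **kw)


@pytest.fixture(scope="session")
def small_config():
    """A fast generator configuration with every planted feature present."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length_bp=25_000_000,
        n_coding_genes=260,
        n_lncrnas=40,
        fraction_conserved_lnc=0.2,
        fraction_desert_lnc=0.1,
        pair_class_counts=(10, 6, 3, 5),
        n_decoys_per_type=3,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_gene_models(small_config)


@pytest.fixture(scope="session")
def zero_noise_config():
    """Default-size study conditions with the noise turned off."""
    return SimulationConfig(seed=11, noise_sd_log2=0.0)


@pytest.fixture(scope="session")
def zero_noise_sim(zero_noise_config):
    return simulate_gene_models(zero_noise_config)
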