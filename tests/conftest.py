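import pytest

from far_expand.io_annotations import GeneRecord, GenomicInterval, ScaffoldIndex, TERecord
from far_expand.synthetic_data import SimulationConfig, simulate_genome_with_tes


@pytest.fixture
def scaffold_index():
    return ScaffoldIndex({"scaf1": 100_000, "scaf2": 50_000})


@pytest.fixture
def example_gene():
    return GeneRecord("gX", GenomicInterval("scaf1", 50_000, 51_000, "+"), "FAR-A")


@pytest.fixture
def example_tes():
    return [
        TERecord(GenomicInterval("scaf1", 45_000, 47_000), "I", "LINE"),
        TERecord(GenomicInterval("scaf1", 46_000, 48_000), "I", "LTR"),
        TERecord(GenomicInterval("scaf1", 52_000, 54_000), "II", "DNA"),
    ]


@pytest.fixture(scope="session")
def small_genome():
    """A small enriched synthetic genome reused across tests."""
    config = SimulationConfig(seed=11, n_genes=60, n_focal=8, n_nonfocal=6, n_scaffolds=4)
    return config, simulate_genome_with_tes(config)
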