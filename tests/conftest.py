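import pytest

from bicistron.io_formats import GeneAnnotation, TranscriptIsoform
from bicistron.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study conditions, shared by
    the recovery tests (generation is deterministic for a fixed seed)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("A", "chrI", 120, 200, "+"),
        GeneAnnotation("B", "chrI", 250, 480, "+"),
        GeneAnnotation("C", "chrI", 250, 480, "-"),
        GeneAnnotation("D", "chrI", 90, 200, "+"),
        GeneAnnotation("E", "chrII", 120, 200, "+"),
    ]


def make_isoform(start, end, strand="+", chrom="chrI", count=1):
    return TranscriptIsoform(chrom, strand, start, end, count)
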