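import pytest

from codonlogo.alignment_io import Alignment, SequenceRecord
from codonlogo.fixture_gen import ProfileSpec, generate_alignment


def make_alignment(seqs, ids=None):
    """Build an Alignment from raw sequence strings."""
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    return Alignment([SequenceRecord(i, s) for i, s in zip(ids, seqs)])


@pytest.fixture
def tiny_alignment():
    """Two-record minimal valid alignment."""
    return make_alignment(["ATGAAA", "ATGAAG"])


@pytest.fixture
def conserved_alignment():
    """40 identical unambiguous sequences: fully conserved everywhere."""
    return make_alignment(["ATGGCACGT"] * 40)


@pytest.fixture
def fixture_40x10():
    """Seeded 40-sequence, 10-codon alignment with mixed conservation."""
    dists = [{"ATG": 1.0}] + [
        {"AAA": 0.5, "GAA": 0.3, "CAA": 0.2} for _ in range(8)
    ] + [{"TGA": 0.75, "TAA": 0.25}]
    spec = ProfileSpec(n_sequences=40, distributions=dists, seed=1234)
    return generate_alignment(spec)
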