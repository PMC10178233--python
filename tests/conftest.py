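import numpy as np
import pytest

from its2gc.io_seqstruct import SeqStructRecord, SpeciesMatrix


def make_records(seqs, structure, counts=None, prefix="a"):
    counts = counts or [1] * len(seqs)
    return [
        SeqStructRecord(id=f"{prefix}{i + 1}", sequence=s, structure=structure,
                        copy_count=c)
        for i, (s, c) in enumerate(zip(seqs, counts))
    ]


@pytest.fixture
def small_matrix():
    """Four alleles over a 10-column alignment with a 2-pair stem."""
    structure = "((....)).."
    seqs = [
        "GCAUGCAUGC",
        "GCAUGCAUGC",
        "GCAUGAAUGC",
        "GUAUGCAUGC",
    ]
    return SpeciesMatrix(
        species_name="spX",
        records=make_records(seqs, structure, counts=[3, 2, 2, 4]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
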