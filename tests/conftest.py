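import numpy as np
import pytest

from drscan.synthetic_data import CladeSpec, GenomeSpec, generate_clade, generate_genome

#: Fixture GenBank record: 60 bp, one CDS at 1..30, one D-loop at 41..60.
MINI_GENBANK = """\
LOCUS       MINI0001                  60 bp    DNA     circular VRT 01-JAN-2020
DEFINITION  Minimal synthetic mitochondrial fixture.
ACCESSION   MINI0001
VERSION     MINI0001.1
FEATURES             Location/Qualifiers
     source          1..60
                     /organism="synthetic construct"
     CDS             1..30
                     /gene="ND0"
     D-loop          41..60
ORIGIN
        1 atgaaacccg ggtttacgta cgtacgttaa acgtacgtac gttgcatgca tgcatgcatt
//
"""


def small_genome_spec(seed: int = 11, length: int = 4000) -> GenomeSpec:
    """A compact genome spec used across tests (fast to scan, full layout)."""
    return GenomeSpec(length=length, dloop_length=300, rrna_lengths=(250, 350),
                      seed=seed)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(small_genome_spec())


@pytest.fixture(scope="session")
def small_clade():
    return generate_clade(
        CladeSpec(n_leaves=10, seed=23),
        small_genome_spec(seed=23, length=3500),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
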