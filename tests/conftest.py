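import numpy as np
import pytest

from apmskit import ProteinRecord, SampleMeta, SpectralCountTable


def make_design(n_rep=3):
    return [
        SampleMeta(f"bait_{r}", "bait", r) for r in range(1, n_rep + 1)
    ] + [
        SampleMeta(f"ctrl_{r}", "control", r) for r in range(1, n_rep + 1)
    ]


def make_table(spc, unique_peptides=None, n_rep=None, accessions=None):
    """Build a SpectralCountTable from a (proteins x 2*n_rep) array.

    Columns are bait replicates then control replicates.
    """
    spc = np.asarray(spc, dtype=np.int64)
    n_rep = n_rep or spc.shape[1] // 2
    if accessions is None:
        accessions = [f"P{i + 1}" for i in range(spc.shape[0])]
    if unique_peptides is None:
        unique_peptides = spc.copy()
    return SpectralCountTable(
        proteins=[ProteinRecord(a, gene_symbol=a) for a in accessions],
        samples=make_design(n_rep),
        spc=spc,
        unique_peptides=np.asarray(unique_peptides, dtype=np.int64),
    )


@pytest.fixture
def design3():
    return make_design(3)
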