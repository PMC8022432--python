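import numpy as np
import pytest

from codonopt.genome_io import CdsRecord


def make_cds(gene_id: str, codons) -> CdsRecord:
    """Build a validated CdsRecord straight from a codon list."""
    codons = tuple(codons)
    seq = "".join(codons)
    return CdsRecord(gene_id=gene_id, seq=seq, codons=codons, length_nt=len(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_cds(rng):
    """A bag of random CDS records over the 61 sense codons."""
    from codonopt.genetic_code import STANDARD_CODE

    sense = STANDARD_CODE.sense_codons

    def _make(n_genes=30, n_codons=120):
        return [
            make_cds(f"g{i}", rng.choice(sense, size=n_codons))
            for i in range(n_genes)
        ]

    return _make
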