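import numpy as np
import pytest

from cognate.genome import GeneRecord, GenomeTable


def make_table(n_genes: int, strain: str = "s0", replicon: str = "chr", seed: int = 0) -> GenomeTable:
    """A linear replicon of n random proteins, 1 kb apart."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    genes = []
    for i in range(n_genes):
        seq = "".join(rng.choice(aas, size=60))
        genes.append(
            GeneRecord(
                gene_id=f"{strain}__g{i:03d}",
                strain_id=strain,
                replicon_id=replicon,
                start=1 + i * 1000,
                end=200 + i * 1000,
                strand="+" if i % 2 else "-",
                ordinal=i,
                protein_seq=seq,
            )
        )
    return GenomeTable(strain_id=strain, replicons={replicon: genes})


@pytest.fixture
def table21() -> GenomeTable:
    return make_table(21)


@pytest.fixture
def random_protein():
    rng = np.random.default_rng(7)
    aas = list("ACDEFGHIKLMNPQRSTVWY")

    def make(length: int) -> str:
        return "".join(rng.choice(aas, size=length))

    return make
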