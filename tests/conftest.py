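import numpy as np
import pytest

from stallscan.core import CodingRegion


def make_gene(gene_id: str, n_codons: int, background: str = "GCT",
              substitutions: dict[int, str] | None = None,
              stop: str = "TAA") -> CodingRegion:
    """A CDS of `n_codons` coding codons (incl. ATG) + stop, with specific
    codons substituted at given 0-based codon indices."""
    codons = ["ATG"] + [background] * (n_codons - 1)
    for idx, codon in (substitutions or {}).items():
        codons[idx] = codon
    return CodingRegion(gene_id, "".join(codons) + stop)


@pytest.fixture
def poly_lysine_gene() -> CodingRegion:
    return make_gene("polyK", 100, background="AAA")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
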