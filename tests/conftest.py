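import pytest

from degenphy import Msa, ScoreScheme, build_code, expand_matrix


@pytest.fixture(scope="session")
def standard_code():
    return build_code(1)


@pytest.fixture(scope="session")
def default_scheme():
    return ScoreScheme()


@pytest.fixture(scope="session")
def default_matrix(default_scheme):
    return expand_matrix(default_scheme)


@pytest.fixture
def one_codon_msa():
    """S1/S2 are synonymous Leu codons; S3 is a Phe codon."""
    return Msa([("S1", "CTC"), ("S2", "TTG"), ("S3", "TTC")])
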