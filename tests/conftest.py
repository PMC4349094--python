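import pytest
from hypothesis import settings

from emcsim.digestion import load_profile
from emcsim.synthetic_data import (
    design_deletion,
    generate_amplicon,
    make_complex_allele,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def exon2a():
    return generate_amplicon("exon2a")


@pytest.fixture(scope="session")
def exon3():
    return generate_amplicon("exon3")


@pytest.fixture(scope="session")
def exon6():
    return generate_amplicon("exon6")


@pytest.fixture(scope="session")
def del20_exon3(exon3):
    return design_deletion(exon3)


@pytest.fixture(scope="session")
def d15(exon2a):
    return make_complex_allele(exon2a, "D15")


@pytest.fixture(scope="session")
def d19(exon2a):
    return make_complex_allele(exon2a, "D19")


@pytest.fixture(scope="session")
def t7e1():
    return load_profile("t7e1")


@pytest.fixture(scope="session")
def surveyor():
    return load_profile("surveyor")
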