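import pytest

from beetyping.assay_design import load_assays
from beetyping.insilico_pcr import load_primers
from beetyping.restriction import builtin_enzymes
from beetyping.synthetic_data import DEFAULT_SEED, generate_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The default-seed validated synthetic haplotype set."""
    return generate_fixtures(DEFAULT_SEED)


@pytest.fixture(scope="session")
def primers():
    return load_primers()


@pytest.fixture(scope="session")
def enzymes():
    return builtin_enzymes()


@pytest.fixture(scope="session")
def assays():
    return load_assays()
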