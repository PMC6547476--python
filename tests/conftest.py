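import pytest

from fqarc.synthetic import fixture_matrix


@pytest.fixture(scope="session")
def matrix():
    """The deterministic synthetic fixture suite (generated once per run)."""
    return fixture_matrix()


@pytest.fixture(scope="session")
def illumina_fastq(matrix):
    """A correlated Illumina-like fixture with repeats and bare plus lines."""
    return matrix["illumina_bare_n00"]


@pytest.fixture(scope="session")
def pacbio_fastq(matrix):
    """A variable-length PacBio-like fixture."""
    return matrix["pacbio_bare_n001"]
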