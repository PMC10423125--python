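import pytest

from aars_symmetry import (
    default_classification,
    isometry_group,
    standard_code,
)


@pytest.fixture(scope="session")
def table():
    return standard_code()


@pytest.fixture(scope="session")
def classification():
    return default_classification()


@pytest.fixture(scope="session")
def full_group():
    """The full hyperoctahedral group of the 6-cube, order 46,080."""
    return isometry_group(6, "full")


@pytest.fixture(scope="session")
def structured_group():
    """The position-respecting subgroup, order 3,072."""
    return isometry_group(6, "codon-structured")
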