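import pytest

from mtsticks import AxonGeometry, SummaryStats


@pytest.fixture
def wt_summary() -> SummaryStats:
    """Printed wild-type TEM summary: mean 67, sd 9, 8 sections."""
    return SummaryStats(mean=67.0, sd=9.0, n=8)


@pytest.fixture
def mut_summary() -> SummaryStats:
    """Printed elongator-mutant TEM summary: mean 85, sd 5, 8 sections."""
    return SummaryStats(mean=85.0, sd=5.0, n=8)


@pytest.fixture
def axon() -> AxonGeometry:
    return AxonGeometry(100.0, "circular")
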