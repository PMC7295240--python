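import pytest
from hypothesis import HealthCheck, settings

from miningd import CDR3Set, GermlineDB
from miningd.io import GermlineEntry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_cdr3s() -> CDR3Set:
    return CDR3Set.from_sequences(
        ["ACGTACGTACGT", "ACGTACGTACGT", "TTTTGGGGCCAA", "ACGTACGTACGA"],
        label="toy",
    )


@pytest.fixture
def toy_db() -> GermlineDB:
    return GermlineDB(
        entries=[
            GermlineEntry("d1", "01", "ACGTACGTAC"),
            GermlineEntry("d2", "01", "TTTTGGGGCCAA"),
        ],
        species="toy",
    )


@pytest.fixture
def human_d3_entries() -> list[GermlineEntry]:
    """Two real human D genes used by the classification fixtures."""
    return [
        GermlineEntry("IGHD3-10", "01", "GTATTACTATGGTTCGGGGAGTTATTATAAC"),
        GermlineEntry("IGHD3-16", "02", "GTATTATGATTACGTTTGGGGGAGTTATCGTTATACC"),
    ]
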