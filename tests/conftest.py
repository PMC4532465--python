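from hypothesis import HealthCheck, settings
import pytest

from crtscan import DetectionTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> DetectionTable:
    """One animal, one receiver, gaps 4 / 8 / 18 time units."""
    return DetectionTable.from_records(
        [("A", "f1", 0), ("A", "f1", 4), ("A", "f1", 12), ("A", "f1", 30)],
        time_unit="step",
    )


@pytest.fixture
def two_receiver_table() -> DetectionTable:
    """Two animals moving between receivers, with a same-time tie."""
    return DetectionTable.from_records(
        [
            ("A", "f1", 0),
            ("A", "f1", 10),
            ("B", "f1", 100),
            ("B", "f1", 101),
            ("A", "f2", 3),
            ("B", "f2", 3),
            ("B", "f2", 20),
        ],
        time_unit="step",
    )
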