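import pytest

from seedscape.schedule import schedule_from_events


@pytest.fixture
def example_schedule():
    """20-seed dish with events on days 26 (1 seed), 30 (2) and 35 (1)."""
    return schedule_from_events("d1", "t1", 20, 60, {26: 1, 30: 2, 35: 1})


@pytest.fixture
def empty_schedule():
    return schedule_from_events("d0", "t1", 20, 60, {})
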