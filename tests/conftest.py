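import pytest
from hypothesis import HealthCheck, settings

from gapfill import PairConfig, simulate_pair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def perfect_pair():
    """Zero-error 10 Mb target/donor pair with 20 planted gaps (shared)."""
    return simulate_pair(101, PairConfig())


@pytest.fixture(scope="session")
def small_pair():
    """Quick 2 Mb single-sequence pair with 5 gaps for cheap pipeline tests."""
    return simulate_pair(7, PairConfig(n_seqs=1, seq_len=2_000_000, n_gaps=5))
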