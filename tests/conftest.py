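import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def high_matrix():
    from peg3motif import surrogate_high_matrix

    return surrogate_high_matrix()


@pytest.fixture(scope="session")
def low_matrix():
    from peg3motif import surrogate_low_matrix

    return surrogate_low_matrix()


@pytest.fixture(scope="session")
def fold_panel():
    """The validated fold-change panel: two transporter genes, two tissues."""
    return {
        "Slc38a2": {"brain": 2.5, "heart": 5.5},
        "Slc38a4": {"brain": 1.5, "heart": 4.0},
    }
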