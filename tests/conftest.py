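import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def baseline_config():
    from farmers_game.game_core import GameConfig

    return GameConfig(seed=11)


@pytest.fixture
def small_config():
    """A 6x6 run small enough for exhaustive checks."""
    from farmers_game.game_core import GameConfig

    return GameConfig(rows=6, cols=6, rounds=10, seed=11)
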