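import pytest

from explorevar import (
    LearnerParams,
    Model,
    TaskParams,
    draw_noise_vectors,
    simulate_trials,
)


@pytest.fixture(scope="session")
def default_learner():
    return LearnerParams()


@pytest.fixture(scope="session")
def default_task():
    return TaskParams()


@pytest.fixture(scope="session")
def draw_bank():
    """Shared bank of noise draws: 50 simulations of 500 trials."""
    return draw_noise_vectors(n_trials=500, n_sims=50, seed=0)


@pytest.fixture(scope="session")
def default_series(draw_bank, default_learner, default_task):
    """Five default therrien16 simulations (adaptive mean criterion)."""
    return [
        simulate_trials(Model.THERRIEN16, default_learner, default_task, d)
        for d in draw_bank[:5]
    ]
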