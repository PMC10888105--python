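import numpy as np
import pytest

from swarmvote import FixtureSpec, PSOConfig, generate_predictions


@pytest.fixture(scope="session")
def three_model_fixture():
    """M=3 models of accuracies 0.9/0.7/0.5 on a 3-class, 500-sample problem."""
    spec = FixtureSpec(
        n_samples=500,
        n_classes=3,
        n_models=3,
        model_accuracies=(0.9, 0.7, 0.5),
        concentration=8.0,
        pair_correlation=0.3,
        seed=11,
    )
    return generate_predictions(spec)


@pytest.fixture(scope="session")
def perfect_vs_uniform():
    """Two-model set: one near-perfect (0.99 on truth), one exactly uniform."""
    rng = np.random.default_rng(5)
    n, c = 200, 3
    y = rng.integers(0, c, size=n)
    good = np.full((n, c), 0.005)
    good[np.arange(n), y] = 0.99
    uniform = np.full((n, c), 1.0 / c)
    from swarmvote import PredictionSet

    return PredictionSet(("good", "uniform"), np.stack([good, uniform])), y


@pytest.fixture
def fast_pso():
    """Reduced schedule for unit tests that only exercise mechanics."""
    return PSOConfig(n_particles=30, max_iterations=120, seed=3)
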