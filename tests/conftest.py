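import pytest
from hypothesis import HealthCheck, settings

from oligoforce.detect import classify_curve
from oligoforce.simulate import SimulationConfig, simulate_ensemble

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Study-conditions ensemble: generator defaults, 1000 curves, fixed seed.
ENSEMBLE_SEED = 12345
ENSEMBLE_N = 1000


@pytest.fixture(scope="session")
def default_ensemble():
    """1000 labelled curves at generator defaults (the main test surface)."""
    config = SimulationConfig(n_curves=ENSEMBLE_N, seed=ENSEMBLE_SEED)
    curves, labels, manifest = simulate_ensemble(config)
    return config, curves, labels


@pytest.fixture(scope="session")
def default_classifications(default_ensemble):
    """Detection pipeline applied to the session ensemble."""
    _, curves, _ = default_ensemble
    return [classify_curve(curve) for curve in curves]
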