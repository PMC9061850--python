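import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def logistic(t, A=1000.0, k=2.0, t0=10.0):
    """Noise-free sigmoid A/(1+exp(-k(t-t0))): the canonical ThT shape."""
    return A / (1.0 + np.exp(-k * (t - t0)))


@pytest.fixture
def logistic_curve():
    """A fine-grid logistic ThT curve with known closed-form kinetics."""
    from amykin.kinetics import ThTCurve

    t = np.linspace(0.0, 30.0, 1501)
    return ThTCurve(t=t, y=logistic(t)), dict(A=1000.0, k=2.0, t0=10.0)


@pytest.fixture
def exchange_model():
    from amykin.synthetic import default_exchange_model

    return default_exchange_model()
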