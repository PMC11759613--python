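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

from ppct import TrialData  # noqa: E402


@pytest.fixture
def toy() -> TrialData:
    """Four-subject trial with hand-computable moments.

    Treated: y = [3, 5], f = [2, 4]; controls: y = [1, 3], f = [1, 3].
    Reference ATE = 2, prediction-residual ATE = 1, per-arm SDs sqrt(2),
    perfect within-arm outcome-score correlation.
    """
    return TrialData(y=[3, 5, 1, 3], t=[1, 1, 0, 0], f=[2, 4, 1, 3])


def random_trial(seed: int, m: int = 17, n: int = 13, rho: float = 0.6) -> TrialData:
    """A generic correlated trial dataset for property tests."""
    rng = np.random.default_rng(seed)
    yc = rng.normal(0.0, 1.5, m + n)
    t = np.zeros(m + n, dtype=int)
    t[rng.permutation(m + n)[:m]] = 1
    y = yc + 0.8 * t
    f = rho * yc + np.sqrt(1 - rho**2) * rng.normal(0, 1.5, m + n) + rng.normal(2.0, 0.3)
    return TrialData(y=y, t=t, f=f)
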