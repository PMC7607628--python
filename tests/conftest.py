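import numpy as np
import pytest
from scipy import integrate, stats

from pi3ktrial.design import BetaDistribution, MonitoringRule


@pytest.fixture
def study_rule() -> MonitoringRule:
    """The protocol monitoring rule: Beta(0.5, 9.5) prior, p_ref 0.05,
    threshold 0.95, interim at 29 of 50."""
    return MonitoringRule(
        prior=BetaDistribution(0.5, 9.5),
        p_ref=0.05,
        threshold=0.95,
        interim_n=29,
        total_n=50,
    )


def beta_cdf_quadrature(alpha: float, beta_: float, p: float) -> float:
    """Independent adaptive-quadrature oracle for the beta CDF."""
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, alpha, beta_), 0.0, p, epsabs=1e-12, limit=200
    )
    return val


@pytest.fixture
def quad_oracle():
    return beta_cdf_quadrature


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
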