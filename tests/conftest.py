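import numpy as np
import pytest

from satkin import SaturationCurve, SimSpec, generate


@pytest.fixture
def curve():
    """The workhorse curve: kappa0=2, y_sat=10, K=5."""
    return SaturationCurve(kappa0=2.0, y_sat=10.0)


@pytest.fixture
def unit_curve():
    return SaturationCurve(kappa0=1.0, y_sat=1.0)


@pytest.fixture
def noiseless_data(curve):
    """12 exact points on the workhorse curve, geometric span [K/5, 10K]."""
    return generate(SimSpec(curve=curve, n_points=12, seed=0))


def random_curves(n, seed=0, decades=3):
    """Valid curves with log-uniform constants over 10^[-decades, decades].

    The model is scale invariant, so narrower ranges probe the same
    mathematics with less floating-point headroom consumed by 1/x terms.
    """
    rng = np.random.default_rng(seed)
    k0, ys = 10 ** rng.uniform(-decades, decades, size=(2, n))
    return [SaturationCurve(kappa0=a, y_sat=b) for a, b in zip(k0, ys)]
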