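import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from rbakit import AnalysisSettings, Medium
from rbakit import toys

hyp_settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("ci")


@pytest.fixture
def settings():
    return AnalysisSettings()


@pytest.fixture
def self_replicator():
    """kE = kR = 2, unit weights: closed-form mu_max = 1."""
    return toys.make_self_replicator(kE=2, kR=2, n_E=1, n_R=1, D=1)


@pytest.fixture
def pinned():
    """kE = kR = 2, unit weights, c0 = 0.2, D = 1: mu_max = 0.8, unique optimum."""
    return toys.make_pinned_replicator(kE=2, kR=2, n_E=1, n_R=1, n_H=1, c0=0.2, D=1)


@pytest.fixture
def importer():
    """MM importer, vmax=2, km=0.1: mu_max(km) = 8/15, plateau 0.8."""
    return toys.make_mm_importer(vmax=2, km=0.1, kR=2, c0=0.2, D=1)


@pytest.fixture
def importer_medium():
    return Medium({"nutrient_ext": 0.1})


@pytest.fixture
def overflow():
    return toys.make_overflow_branch()


@pytest.fixture
def overflow_medium():
    return Medium({"substrate_ext": 1.0, "byproduct_ext": 0.0})


@pytest.fixture
def secretion():
    return toys.make_secretion()


def dense_mu_max(model, medium=None, n_points=2000, mu_hi=None, settings=None):
    """Brute-force oracle: largest feasible growth rate on a dense grid.

    Independent of the bisection: scans a uniform grid and returns the last
    feasible point (resolution mu_hi / (n_points - 1)).
    """
    from rbakit import is_feasible, maximize_growth

    settings = settings or AnalysisSettings()
    if mu_hi is None:
        mu_hi = 2.0 * max(maximize_growth(model, medium, settings).mu, settings.bisection_tol)
    grid = np.linspace(0.0, mu_hi, n_points)
    best = 0.0
    for mu in grid:
        if is_feasible(model, float(mu), medium, settings):
            best = float(mu)
    return best, mu_hi / (n_points - 1)
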