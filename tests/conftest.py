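import pytest
from hypothesis import settings

from cngperm import fitting, kinetics, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_profile():
    """One-ion synthetic free-energy profile (four minima, plateau at 2 nm)."""
    return synthetic.make_profile(synthetic.DEFAULT_SINGLE)


@pytest.fixture(scope="session")
def double_profile():
    """Two-ion synthetic profile (one shallow well, plateau at 1 nm)."""
    return synthetic.make_profile(synthetic.DEFAULT_DOUBLE)


@pytest.fixture(scope="session")
def default_rates():
    return kinetics.TwoSiteRates()


@pytest.fixture(scope="session")
def fig4_dataset():
    """Default noisy conductance dataset (activities attached by generation)."""
    return synthetic.make_conductance(synthetic.DEFAULT_FIG4)


@pytest.fixture(scope="session")
def fig4_noiseless():
    from dataclasses import replace

    spec = replace(synthetic.DEFAULT_FIG4, noise_cv=0.0)
    return synthetic.make_conductance(spec)
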