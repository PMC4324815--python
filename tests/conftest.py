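import numpy as np
import pytest

from fitfatigue import (
    ClimbSession,
    CohortDesign,
    FitConfig,
    ModelParams,
    TrainingSeries,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_series(rng, n_days=30, rat_id="r1", p_scale=1.0):
    """A random daily impulse series with measurements on impulse days."""
    w = np.where(rng.random(n_days) < 0.6, rng.uniform(10, 100, n_days), 0.0)
    days = np.flatnonzero(w) + 1
    if days.size == 0:
        w[0] = 50.0
        days = np.array([1])
    return TrainingSeries(
        rat_id=rat_id,
        w=w,
        measured_days=days,
        p_obs=rng.uniform(0.5, 2.0, days.size) * p_scale,
    )


@pytest.fixture
def series_factory(rng):
    return lambda **kw: random_series(rng, **kw)


def random_params(rng, variant, sign="plus"):
    common = dict(
        p0=rng.uniform(0.2, 2.0),
        k1=rng.uniform(0.001, 0.05),
        tau1=rng.uniform(1.0, 20.0),
    )
    if variant == "1comp":
        return ModelParams(variant="1comp", **common)
    if variant == "2comp":
        return ModelParams(
            variant="2comp",
            k2=rng.uniform(0.001, 0.05),
            tau2=rng.uniform(1.0, 20.0),
            **common,
        )
    return ModelParams(
        variant="3comp",
        tau2=rng.uniform(1.0, 20.0),
        k2_0=rng.uniform(0.001, 0.05),
        k3=rng.uniform(1e-6, 1e-4),
        tau3=rng.uniform(1.0, 20.0),
        third_sign=sign,
        **common,
    )


@pytest.fixture
def params_factory(rng):
    return lambda variant, **kw: random_params(rng, variant, **kw)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortDesign(), seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(CohortDesign(noise_sd=0.0), seed=7)


@pytest.fixture
def fast_config():
    return FitConfig(n_starts=4, seed=0)


@pytest.fixture
def climb_session():
    return ClimbSession(
        rat_id="r1",
        day=1,
        body_mass=0.2876,
        load_mass=0.1438,
        climb_height=1.0,
        repetitions=10,
        total_time=100.0,
    )
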