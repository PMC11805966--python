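import numpy as np
import pytest

import compositesem as cs


@pytest.fixture(scope="session")
def pop_model():
    return cs.illustrative_fixture()


@pytest.fixture(scope="session")
def spec(pop_model):
    return pop_model.spec


@pytest.fixture(scope="session")
def moments180(pop_model):
    """One fixed-seed simulated sample of n = 180 from the population."""
    _, moments = cs.simulate_sample(pop_model, 180, seed=42)
    return moments


@pytest.fixture(scope="session")
def pop_moments(pop_model):
    """The population covariance itself, treated as a sample of n = 180."""
    return pop_model.population_moments(180)


@pytest.fixture(scope="session")
def fits180(spec, moments180):
    """All five variants fitted to the shared n = 180 sample."""
    out = {}
    for variant in ("unit", "free", "relaxed", "one_step", "two_step"):
        est = cs.CompositeSEM(model=spec, variant=variant, seed=3)
        est.fit(moments180)
        out[variant] = est
    return out


def std_map(est_or_fit):
    """Standardized structural solution keyed by (source, target, role)."""
    if hasattr(est_or_fit, "standardized_solution_"):
        sol = est_or_fit.standardized_solution_(with_se=False)
    else:
        sol = cs.standardized_solution(est_or_fit)
    return {(r.source, r.target, r.role): r.std for r in sol.itertuples()}
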