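import numpy as np
import pytest

import validcorr as vc

SCENARIO = dict(rho_yx1=0.60, rho_yx2=0.20, rho_x1x2=0.00)


@pytest.fixture(scope="session")
def scenario_spec():
    """The illustrative trivariate scenario: rho = (.60, .20, .00), N = 1000."""
    return vc.CorrelationSpec(n_applicants=1000, **SCENARIO)


@pytest.fixture(scope="session")
def selected_pool(scenario_spec):
    """One N=1000 pool with top-20% selection applied (seed fixed)."""
    pool = vc.generate_applicants(scenario_spec, seed=20240101)
    return vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, 0.2))


@pytest.fixture(scope="session")
def monotone_fixture():
    """N=1000 pool, 40% selected, i.e. 60% of outcomes missing at random."""
    spec = vc.CorrelationSpec(n_applicants=1000, **SCENARIO)
    pool = vc.generate_applicants(spec, seed=77)
    return vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, 0.4))


@pytest.fixture(scope="session")
def big_selected_pool():
    """Large pool (n=200k) under 20% compensatory selection for geometry checks."""
    spec = vc.CorrelationSpec(n_applicants=200_000, **SCENARIO)
    pool = vc.generate_applicants(spec, seed=4242)
    return pool, vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, 0.2))


@pytest.fixture(scope="session")
def study_300():
    """Shared scaled-down Monte Carlo study: 300 replications, all methods."""
    cfg = vc.StudyConfig(
        spec=vc.CorrelationSpec(n_applicants=1000, **SCENARIO),
        rates=(0.3, 0.2, 0.1),
        n_reps=300,
        seed=90210,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # slow-tail EM convergence warnings
        return vc.run_study(cfg)
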