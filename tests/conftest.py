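import pytest

from eyebrain0d import default_parameters, make_scenario, solve_steady_state


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (audited calibration profile)."""
    return default_parameters()


@pytest.fixture(scope="session")
def earth_solution(params):
    """The physiological (Earth, pi_c = 25 mmHg) steady state."""
    return solve_steady_state(params, make_scenario("EARTH", 25.0))


@pytest.fixture(scope="session")
def experiment(params):
    """Full four-scenario oncotic sweep with collapse onsets (shared by the
    scenario-level tests; takes a few seconds)."""
    from eyebrain0d.scenarios import run_experiment
    return run_experiment(params)
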