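import numpy as np
import pytest

import nimargin as nm


@pytest.fixture(scope="session")
def scenario() -> nm.Scenario:
    return nm.default_scenario()


@pytest.fixture(scope="session")
def trial() -> nm.TrialDesign:
    return nm.default_trial()


@pytest.fixture(scope="session")
def std_trace(scenario):
    return nm.evaluate_arm(scenario, scenario.standard, scenario.p_S)[0]


def make_trace(n: int = 12, delta: float = 1.0 / 12.0, start_age: float = 50.0, **overrides):
    """Hand-built minimal CohortTrace for accounting unit tests."""
    arrays = dict(
        ages=start_age + delta * np.arange(n + 1),
        cycle_length=delta,
        alive=np.ones(n + 1),
        diagnosed=np.zeros(n + 1),
        dead_other=np.zeros(n + 1),
        dead_crc=np.zeros(n + 1),
        dead_complication=np.zeros(n + 1),
        exams=np.zeros(n),
        new_diagnoses=np.zeros(n),
        complication_deaths=np.zeros(n),
        pt_susceptible=np.full(n, delta),
        pt_diag_initial=np.zeros(n),
        pt_diag_continuing=np.zeros(n),
        pt_diag_cured=np.zeros(n),
        pt_diag_terminal=np.zeros(n),
        discount=np.ones(n),
    )
    arrays.update(overrides)
    return nm.CohortTrace(**arrays)
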