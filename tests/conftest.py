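import numpy as np
import pytest

from resistfam.cohort import Group, TumorTimecourse
from resistfam.resistance_models import DoseSchedule


@pytest.fixture
def weekly_schedule():
    return DoseSchedule(dose=5.0, interval=7.0, n_doses=9)


@pytest.fixture
def growing_tc():
    times = np.array([0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0])
    volumes = 200.0 * np.exp(0.05 * times)
    return TumorTimecourse("m1", Group.control, times, volumes)


@pytest.fixture
def treated_tc():
    """Noiseless model-1.1 trajectory under weekly 5 mg/kg dosing."""
    from resistfam.resistance_models import ResistanceSpec, simulate_treatment

    times = np.array([0.0, 3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 28.0])
    spec = ResistanceSpec("1.1")
    params = {"r_S": 0.1, "lam_S": 0.05, "S0": 200.0}
    sched = DoseSchedule(dose=5.0, interval=7.0, n_doses=5)
    traj = simulate_treatment(spec, params, sched, times)
    return TumorTimecourse("t1", Group.treatment, times, traj.V)
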