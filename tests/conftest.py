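import numpy as np
import pytest

import vmrkit as v


@pytest.fixture(scope="session")
def standard_schedule():
    return v.build_paradigm_schedule(v.ParadigmParams(paradigm="standard"), seed=3)


@pytest.fixture(scope="session")
def savings_schedule():
    return v.build_paradigm_schedule(v.ParadigmParams(paradigm="savings"), seed=3)


@pytest.fixture(scope="session")
def noiseless_params():
    return v.ParticipantParams(
        motor_noise_sd_deg=0.0, rt_noise_sd_ms=0.0, mt_noise_sd_ms=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noiseless_session(standard_schedule, noiseless_params):
    return v.simulate_session(standard_schedule, noiseless_params)


def make_trajectory(angle_deg, radial_disp=1.0, n=50, start=(0.0, 0.0), target_dir_deg=0.0):
    """Straight-line reach at ``target_dir_deg + angle_deg`` from start."""
    theta = np.radians(target_dir_deg + angle_deg)
    radii = np.linspace(0.0, radial_disp * 1.05, n)
    return [
        (i * 10.0, start[0] + r * np.cos(theta), start[1] + r * np.sin(theta))
        for i, r in enumerate(radii)
    ]
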