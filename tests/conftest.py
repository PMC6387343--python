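import dataclasses

import numpy as np
import pytest

from sitstandgo import CohortSpec, draw_subject_params, simulate_30cst, simulate_tug
from sitstandgo.synthetic import subject_rng

FS = 100.0


@pytest.fixture(scope="session")
def default_params():
    """One mid-population subject drawn deterministically."""
    spec = CohortSpec(n_subjects=2, seed=7)
    return draw_subject_params(0.5, spec, subject_rng(7, 1, 0), "S000")


@pytest.fixture(scope="session")
def quiet_params(default_params):
    """Noise-free subject with equal 1 s transitions and 1 s holds."""
    return dataclasses.replace(
        default_params, sts_duration_mean=1.0, st2si_duration_mean=1.0,
        sts_duration_sd=0.0, st2si_duration_sd=0.0,
        stand_hold=1.0, sit_hold=1.0, noise_sd_acc=0.0, noise_sd_gyr=0.0)


@pytest.fixture(scope="session")
def quiet_cst(quiet_params):
    return simulate_30cst(quiet_params, FS, subject_rng(7, 2, 0))


@pytest.fixture(scope="session")
def default_cst(default_params):
    return simulate_30cst(default_params, FS, subject_rng(7, 2, 1))


@pytest.fixture(scope="session")
def default_tug(default_params):
    return simulate_tug(default_params, FS, subject_rng(7, 3, 0))


@pytest.fixture(scope="session")
def quiet_tug(quiet_params):
    return simulate_tug(quiet_params, FS, subject_rng(7, 3, 1))
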