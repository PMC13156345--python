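import numpy as np
import pytest
from dataclasses import replace

from crosspk import (
    ConcentrationTimeProfile,
    letrozole_parameters,
    letrozole_study_design,
    nicotine_parameters,
    nicotine_study_design,
    simulate_profile,
)
from crosspk.simulate import EXTENDED_TIMES_H, STUDY_DAY_TIMES_H, UNINHIBITED


def make_profile(times, conc, analyte="x", dose=None, censored=None):
    return ConcentrationTimeProfile(
        analyte=analyte,
        times_h=np.asarray(times, dtype=float),
        conc_nM=np.asarray(conc, dtype=float),
        censored=None if censored is None else np.asarray(censored, dtype=bool),
        dose_nmol=dose,
    )


@pytest.fixture(scope="session")
def nicotine_params():
    return nicotine_parameters()


@pytest.fixture(scope="session")
def letrozole_params():
    return letrozole_parameters()


@pytest.fixture(scope="session")
def study_times():
    return np.array(STUDY_DAY_TIMES_H)


@pytest.fixture(scope="session")
def extended_times():
    return np.array(EXTENDED_TIMES_H)


@pytest.fixture(scope="session")
def nicotine_noise_free(nicotine_params, study_times):
    """Noise-free concentration curves of the default nicotine cascade."""
    return simulate_profile(nicotine_params, UNINHIBITED, study_times)


@pytest.fixture(scope="session")
def nicotine_profiles(nicotine_params, study_times, nicotine_noise_free):
    conc = nicotine_noise_free
    return {
        "nicotine": make_profile(
            study_times, conc["nicotine"], "nicotine", dose=nicotine_params.dose_nmol
        ),
        "cotinine": make_profile(study_times, conc["cotinine"], "cotinine"),
        "3-hydroxycotinine": make_profile(
            study_times, conc["3-hydroxycotinine"], "3-hydroxycotinine"
        ),
    }


def noise_free_design(maker, **kwargs):
    """A study design with residual error, period variability and LOQ disabled."""
    design = maker(intra_cv=0.0, prop_error_cv=0.0, **kwargs)
    return replace(design, loq_nM=0.0)
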