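import numpy as np
import pytest
from hypothesis import settings

from ecgrecon import SynthConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def global_cohort():
    """Noiseless cohort with one full-rank mixing matrix: every lead is an
    exact linear function of I, II, V3."""
    return generate_cohort(SynthConfig(n_patients=20, seed=101))


@pytest.fixture(scope="session")
def per_wave_cohort():
    """Noiseless cohort with wave-specific mixing: the 3-lead linear model is
    misspecified by construction, the 6-channel masked model is exact."""
    return generate_cohort(
        SynthConfig(n_patients=12, mixing_mode="per_wave", disparity=0.2, seed=202)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Global-mixing cohort with 20 dB additive white noise."""
    return generate_cohort(SynthConfig(n_patients=8, noise_snr_db=20, seed=303))


def stack_leads(cohort, leads):
    return np.vstack([it.record.subset(leads) for it in cohort.items])


def stack_augmented(cohort):
    from ecgrecon import build_augmented_input

    return np.vstack(
        [build_augmented_input(it.record, it.fiducials).to_matrix() for it in cohort.items]
    )


P2_INPUTS = ("I", "II", "V3")
P2_OUTPUTS = ("V1", "V2", "V4", "V5", "V6")
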