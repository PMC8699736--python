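import numpy as np
import pytest

from svagree.simulate import (
    DeviceModel,
    ProtocolConfig,
    RespondentProfile,
    make_return,
    simulate_cohort,
)

#: grid used throughout: 0..60% fall in 10% steps
GRID = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@pytest.fixture
def identity_device():
    return DeviceModel(name="ideal")


@pytest.fixture
def noise_free_config():
    return ProtocolConfig(
        n_subjects=4,
        baseline_sv_sd=0.0,
        within_step_cv=0.0,
        ref_cv=0.0,
        seed=0,
    )


@pytest.fixture
def noise_free_cohort(noise_free_config, identity_device):
    return simulate_cohort(noise_free_config, [identity_device])


def uniform_returns(n, thresholds=(20.0, 40.0), grid=GRID, noise=0.0, rng=None):
    """n questionnaire returns from identical-threshold respondents."""
    profiles = [
        RespondentProfile(
            respondent_id=f"r{i}",
            threshold_action_indicated=thresholds[0],
            threshold_action_essential=thresholds[1],
            rating_noise=noise,
        )
        for i in range(n)
    ]
    return [make_return(p, grid, rng) for p in profiles]


@pytest.fixture
def fifteen_identical_returns():
    return uniform_returns(15)
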