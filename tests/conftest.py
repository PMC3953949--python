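import numpy as np
import pytest

from glomplast import synthetic_data as sd


@pytest.fixture
def perfect_behavior_gt():
    return sd.BehaviorGroundTruth(
        dilution_exponents=[0],
        p_correct_by_dilution={0: 1.0},
        divergence_time_ms=400.0,
        n_trials=300,
        seed=11,
    )


@pytest.fixture
def chance_behavior_gt():
    return sd.BehaviorGroundTruth(
        dilution_exponents=[0],
        p_correct_by_dilution={0: 0.5},
        n_trials=1000,
        seed=7,
    )


@pytest.fixture
def noiseless_imaging_gt():
    """One glomerulus of exactly -2 permil, no vessels, no noise."""
    return sd.ImagingGroundTruth(
        field_shape=(32, 32),
        glomeruli=[sd.Glomerulus(center=(16.0, 16.0), radius=3.0, base_amplitude={"A": -2.0})],
        noise_sd_permil=0.0,
        seed=0,
    )


def disk_pixels(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.argwhere(mask)
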