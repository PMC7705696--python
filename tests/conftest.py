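import numpy as np
import pytest

from fibrilsans import (
    FitConfig,
    SyntheticSpec,
    WoodModelParams,
    fit_equatorial,
    generate_frames,
    reduce_frames,
)

# Study-condition ground truth used across the suite: native-softwood-like
# spacing (a_cc = 43 A -> 4.3 nm) and bundle diameter 18.5 nm
FLAGSHIP_TRUTH = WoodModelParams(
    a_cc=43.0, sigma_b=2.0 * np.sqrt(2.0) / 185.0
)
FLAGSHIP_D_NM = 18.5

#: default relative noise of synthetic 1D profiles (typical reduced SANS)
DEFAULT_NOISE = 0.03


@pytest.fixture(scope="session")
def flagship_spec():
    return SyntheticSpec(truth=FLAGSHIP_TRUTH, seed=42)


@pytest.fixture(scope="session")
def flagship_frames(flagship_spec):
    frames, record = generate_frames(flagship_spec)
    return frames, record


@pytest.fixture(scope="session")
def flagship_profile(flagship_frames):
    frames, _ = flagship_frames
    return reduce_frames(frames)


@pytest.fixture(scope="session")
def flagship_fit(flagship_profile):
    return fit_equatorial(flagship_profile, FitConfig(seed=7, n_starts=16))
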