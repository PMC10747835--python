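import numpy as np
import pytest
from hypothesis import settings

from cuffsim.signal_model import BeatTemplate, SubjectProfile

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

FS = 200.0


@pytest.fixture(scope="session")
def template() -> BeatTemplate:
    return BeatTemplate.raised_cosine()


@pytest.fixture
def quiet_subject() -> SubjectProfile:
    """Noiseless, jitter-free 80 bpm subject."""
    return SubjectProfile(true_hr_bpm=80.0, hr_jitter_sd=0.0, noise_sd_counts=0.0)


def local_maxima(values: np.ndarray, min_height: float) -> list[int]:
    """Brute-force local-maximum scan used as the offline oracle."""
    return [
        i
        for i in range(1, len(values) - 1)
        if values[i] > values[i - 1] and values[i] >= values[i + 1] and values[i] > min_height
    ]
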