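import numpy as np
import pytest

from savrelease.models import evaluate_release
from savrelease.profiles import ReleaseProfile
from savrelease.synthetic import sampling_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def profile_from_model(model, t_end=400.0, sav=None, times=None):
    """Noise-free profile of a release model on the apparatus schedule."""
    t = sampling_schedule(t_end) if times is None else np.asarray(times, dtype=float)
    c = np.clip(evaluate_release(model, t), 0.0, 100.0)
    return ReleaseProfile(times=t, releases=c, sav=sav)


@pytest.fixture
def make_profile():
    return profile_from_model
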