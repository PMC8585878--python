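import numpy as np
import pytest

from gazeforge.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cfg():
    """A short, cheap experiment used by unit and smoke tests."""
    return SynthConfig(
        n_subjects=6,
        video_duration_s=256.0,
        seed=11,
    )
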