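import numpy as np
import pytest
from hypothesis import settings

from angioffr import CenterlineProfile

settings.register_profile("repro", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("repro")


@pytest.fixture
def uniform_tube():
    """Factory for constant-diameter tube profiles."""

    def make(d=3.0, length=100.0, step=0.5):
        s = np.arange(0.0, length + step / 2, step)
        return CenterlineProfile(s=s, d=np.full_like(s, d))

    return make


@pytest.fixture
def gaussian_lesion_profile():
    """Factory for a tapered vessel with Gaussian diameter dips.

    Each lesion is (center_mm, pct_ds, length_mm); the dip multiplier is
    1 - (pct_ds/100) * exp(-(s-c)^2 / (2 (length/6)^2)).
    """

    def make(lesions, d_prox=3.0, d_dist=None, length=80.0, step=0.1):
        if d_dist is None:
            d_dist = d_prox
        s = np.arange(0.0, length + step / 2, step)
        d = d_prox + (d_dist - d_prox) * s / length
        for center, pct_ds, les_len in lesions:
            sigma = les_len / 6.0
            d = d * (1.0 - pct_ds / 100.0 * np.exp(-((s - center) ** 2) / (2 * sigma**2)))
        return CenterlineProfile(s=s, d=d)

    return make
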