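import numpy as np
import pytest

from punctaquant import Micrograph, PRESETS, generate_field


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def small_condensed_field():
    """One noise-controlled condensed field with ground truth (fast)."""
    fluor, phase, gt = generate_field(
        PRESETS["diauxic"], 20, shading=False, seed=11, shape=(256, 256)
    )
    return fluor, phase, gt


def make_micrograph(pixels, **kw):
    return Micrograph(np.asarray(pixels, dtype=float), **kw)
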