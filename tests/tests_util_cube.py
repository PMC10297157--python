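"""Shared helper: build a minimal registered cube for mosaic/composite tests."""

import numpy as np

from srbpmri.registration import Hypercube


def make_simple_cube(rng, shape=(4, 8, 8)):
    channels = rng.standard_normal((3,) + shape)
    prostate = np.zeros(shape, bool)
    prostate[:, 1:-1, 1:-1] = True
    tumor = np.zeros(shape, bool)
    tumor[shape[0] // 2, 2:4, 2:4] = True
    return Hypercube(
        channels=channels,
        valid=np.ones(shape, bool),
        prostate_mask=prostate,
        tumor_mask=tumor,
        spacing=(3.0, 2.0, 2.0),
        origin=(0.0, 0.0, 0.0),
    )
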