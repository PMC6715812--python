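import numpy as np
import pytest

import glcmrad as gr


@pytest.fixture(scope="session")
def small_phantom():
    """One mid-sized textured tumor phantom on a compact grid."""
    spec = gr.default_class_specs()[1]  # U87-like
    volume, mask = gr.generate_phantom_volume(
        spec, 20.0, (32, 128, 128), seed=7, noise_sd=5.0
    )
    return volume, mask


@pytest.fixture()
def stair_mask():
    """Mask with per-slice areas [0, 5, 12, 9, 3, 1, 0]."""
    areas = [0, 5, 12, 9, 3, 1, 0]
    vox = np.zeros((7, 6, 6), dtype=bool)
    for k, a in enumerate(areas):
        vox[k].flat[:a] = True
    return gr.ROIMask(vox)
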