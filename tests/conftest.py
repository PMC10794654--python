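import numpy as np
import pytest

import oktopo as ok


def disk_mask(shape, center, radius, role=ok.PUPIL):
    """Rasterised disk; center is (x, y) like the package convention."""
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    return ok.RegionMask(
        (((xx - cx) ** 2 + (yy - cy) ** 2) <= radius * radius).astype(np.uint8),
        role=role,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """24 synthetic cases spanning all four classes (fast, shared)."""
    return ok.generate_dataset(24, seed=11)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return ok.TrainConfig(
        learning_rate=1e-4, batch_size=8, epochs=2, input_size_px=32, seed=5
    )
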