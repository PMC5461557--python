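import numpy as np
import pytest

from punctakit import DetectionParams, PunctaSet, VolumeSpec, render_stack


@pytest.fixture
def small_volume():
    return VolumeSpec(20.0, 20.0, 9.0)


@pytest.fixture
def blob_field(small_volume):
    """25 well-separated puncta (pairwise distance > 6x PSF sigma) with a
    noiseless rendered stack — the detection round-trip ground truth."""
    rng = np.random.default_rng(42)
    grid = np.array(
        [(x, y, 4.5) for x in (3.0, 6.5, 10.0, 13.5, 17.0) for y in (3.0, 6.5, 10.0, 13.5, 17.0)]
    )
    points = PunctaSet(grid + rng.uniform(-0.4, 0.4, grid.shape))
    stack = render_stack(points, small_volume)
    return points, stack


@pytest.fixture
def lenient_detection():
    """Detection parameters that keep every candidate (threshold 0)."""
    return DetectionParams(quality_threshold=0.0)
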