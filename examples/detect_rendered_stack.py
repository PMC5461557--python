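"""Round trip: render known puncta into an anisotropic stack, re-detect them.

Renders 25 well-separated puncta as Gaussian blobs on a 60x-like voxel grid
(0.2 x 0.2 x 0.45 um), runs the gamma + Laplacian-of-Gaussian + quality
detector, and reports recall and localization error against the ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

import punctakit as pk

volume = pk.VolumeSpec(20.0, 20.0, 9.0)
rng = np.random.default_rng(42)
grid = np.array(
    [(x, y, 4.5) for x in (3.0, 6.5, 10.0, 13.5, 17.0) for y in (3.0, 6.5, 10.0, 13.5, 17.0)]
)
truth = pk.PunctaSet(grid + rng.uniform(-0.4, 0.4, grid.shape))

stack = pk.render_stack(truth, volume, voxel_size=(0.2, 0.2, 0.45), psf_sigma_um=(0.3, 0.3, 0.6))
# expected diameter of 1 um >= twice the 0.45 um z-step, so the LoG scale is
# resolvable along every axis
detected = pk.detect_spots(
    stack, pk.DetectionParams(gamma=1.79, quality_threshold=0.0, expected_diameter_um=1.0)
)

d, _ = cKDTree(detected.coords).query(truth.coords)
print(f"ground truth: {len(truth)} puncta; detected: {len(detected)}")
print(f"max localization error: {d.max()*1000:.1f} nm "
      f"(voxel diagonal {np.linalg.norm(stack.voxel_size)*1000:.0f} nm)")
print(
    "\nOn a noiseless, well-separated field the detector recovers every punctum\n"
    "with sub-voxel accuracy; the quality threshold (0-100, relative to the\n"
    "strongest spot) is how dim candidates are excluded on real stacks."
)
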