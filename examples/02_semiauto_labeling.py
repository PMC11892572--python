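"""Label a speckled phantom with the statistical boundary detector.

For each layer a threshold mean - alpha * SD is derived from a cuboid region
inside the layer; the first threshold crossing along each A-scan marks the
layer's upper boundary, which is median-smoothed before the next, deeper
layer is processed.
"""

import numpy as np

from octskin import (
    PhantomParams,
    desk_geometry,
    dice,
    render_phantom,
    rois_for_phantom,
    run_semiauto,
)

params = PhantomParams(geometry=desk_geometry(), speckle_shape=8.0, seed=7)
phantom = render_phantom(params)

labels, surfaces = run_semiauto(phantom.volume, rois_for_phantom(params))
report = dice(phantom.truth, labels)

print("per-class DSC vs ground truth:")
for cls, v in report.dsc.items():
    print(f"  class {cls} ({labels.class_names[cls]:10s}): {v:.3f}")
for found, true in zip(surfaces, phantom.boundaries):
    err = np.abs(found.rounded() - true.rounded())
    print(f"boundary of layer {true.layer}: median |dz| = {np.median(err):.1f} voxels")
# DSC near 1 for the thick layers and sub-voxel median boundary error show
# the labeler recovers the planted anatomy despite speckle.
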