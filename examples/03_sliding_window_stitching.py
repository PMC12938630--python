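"""Sliding-window enumeration and prediction stitching.

The detector applies its U-Net to 20x20x16-voxel windows with stride 3
and averages the overlapping per-window predictions back into a
scan-shaped probability volume.
"""

import numpy as np

from cmbdetect import enumerate_windows, stitch_predictions

shape = (26, 20, 16)
origins = enumerate_windows(shape, window=(20, 20, 16), stride=3)
print(f"volume {shape}, window (20,20,16), stride 3 "
      f"-> {len(origins)} windows with x-origins {sorted({o[0] for o in origins})}")

# stitch two synthetic half-confidence windows that overlap
blocks = [(o, np.full((20, 20, 16), 0.2 + 0.2 * i)) for i, o in enumerate(origins)]
pred = stitch_predictions(blocks, shape)
print(f"voxel covered by all three windows: {pred.probabilities[12, 10, 8]:.4f} "
      f"(mean of 0.2, 0.4, 0.6)")
print(f"voxel covered by the first window only: {pred.probabilities[0, 0, 0]:.4f}")
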