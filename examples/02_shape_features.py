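"""Compute the 14 3D shape descriptors of a phantom tumor.

The same code path runs on any BraTS-style segmentation; here the input is a
digitized ball, so the analytic values are known: mesh volume near
(4/3)*pi*r^3 and sphericity near 1 (about 0.91 after voxelization).
"""

import numpy as np

from gliofusion import FEATURE_NAMES, extract_shape_features
from gliofusion.volumes import SegmentationMask

radius = 10
n = 2 * radius + 5
c = n // 2
xs, ys, zs = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
ball = (xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2 <= radius ** 2
mask = SegmentationMask((ball * 2).astype(np.int16), spacing_mm=(1.0, 1.0, 1.0))

vec = extract_shape_features(mask)
for name, value in zip(FEATURE_NAMES, vec.to_array()):
    print(f"{name:24s} {value:10.3f}")
print(f"\nanalytic sphere volume   {4 / 3 * np.pi * radius ** 3:10.3f}")
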