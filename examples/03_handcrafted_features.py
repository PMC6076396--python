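"""Extract the 1056-element handcrafted descriptor from a segmented frame.

Prints the named colour and shape entries, and summarises the Fourier-contour
and texture blocks.  The layout is fixed: 12 colour + 8 shape + 1024 Fourier
+ 12 GLCM values.
"""

import numpy as np

from phenoseq import simulate
from phenoseq.features import extract_features, feature_names

spec = simulate.easy_accession_panel()[1]
rgb, mask = simulate.render_frame(spec, day=16, canvas_size=128, seed=8)
vec = extract_features(rgb, mask)
names = feature_names()

print(f"descriptor length: {len(vec)}")
for i in range(20):  # colour + shape blocks
    print(f"  {names[i]:>14} = {vec[i]:10.3f}")
fourier = vec[20:1044]
print(f"  fourier block: 1024 values, spectral energy {np.sum(fourier**2):.3g}")
for i in range(1044, 1056):
    print(f"  {names[i]:>22} = {vec[i]:8.4f}")
print("Area/perimeter describe size, compactness and eccentricity the rosette "
      "outline, the Fourier block its contour shape, and the GLCM block the "
      "gray-level texture inside the plant.")
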