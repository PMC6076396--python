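"""Segment one rendered frame and compare against the generator's truth mask.

Shows the full pipeline: L*a*b* conversion, per-channel Otsu with a dilation
ring, the 4-level seed mask, GrabCut refinement and morphological cleanup.
Prints the seed-mask level counts and the final intersection-over-union.
"""

import numpy as np
from skimage.color import rgb2lab

from phenoseq import simulate
from phenoseq.segmentation import (channel_trinary_mask, combine_masks,
                                   grabcut_refine, segment_plant, iou)

spec = simulate.easy_accession_panel()[0]
rgb, truth = simulate.render_frame(spec, day=14, canvas_size=128, seed=3)

lab = rgb2lab(rgb)
a8 = np.clip(np.round(lab[:, :, 1] + 128), 0, 255).astype(np.uint8)
b8 = np.clip(np.round(lab[:, :, 2] + 128), 0, 255).astype(np.uint8)
seed = combine_masks(channel_trinary_mask(a8, "low"),
                     channel_trinary_mask(b8, "high"))
levels = dict(zip(*[arr.tolist() for arr in np.unique(seed, return_counts=True)]))
print("seed mask level counts (0 def-bg, 1 def-fg, 2 prob-bg, 3 prob-fg):", levels)

mask = grabcut_refine(rgb, seed)
print(f"refined mask area {mask.sum()} px, truth area {truth.sum()} px")
print(f"IoU vs truth: {iou(mask, truth):.3f}")
print(f"one-call pipeline IoU: {iou(segment_plant(rgb), truth):.3f}")
print("IoU near 1 means the GrabCut refinement recovered the rosette almost "
      "exactly from the colour-seeded initialisation.")
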