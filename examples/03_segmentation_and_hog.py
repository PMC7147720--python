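"""Segment the lesion by adaptive thresholding, then extract HOG features.

The per-pixel threshold is a sensitivity-scaled local mean of the
normalized intensity; keeping the largest connected component and filling
its holes turns the raw binarization into a single lesion mask.  The HOG
descriptor length depends on the cell size — smaller cells encode more
shape information.
"""

import numpy as np

from lesionfuse import synthfixtures as sf
from lesionfuse.hogfeatures import HogParams, compare_cell_sizes
from lesionfuse.preprocess import resize_gray, to_grayscale
from lesionfuse.segmentation import dice_overlap, segment_lesion

SIZE = (280, 384)
rng = np.random.default_rng(5)
spec = sf.random_spec("melanoma", SIZE, rng)
img, truth, _ = sf.generate_lesion_image(spec, SIZE, seed=5)

gray = to_grayscale(img)
mask = segment_lesion(gray)
print(f"segmentation Dice vs ground truth: {dice_overlap(mask, truth):.4f}")

params = HogParams()  # 128x128 window, 4x4 cells, 2x2 blocks, 9 bins
window = resize_gray(gray, *params.window_size)
for row in compare_cell_sizes(window, [(2, 2), (4, 4), (8, 8)], base=params):
    tag = "  <- default" if row["is_default"] else ""
    print(f"cell {row['cell_size']}: descriptor length {row['vector_length']}{tag}")
# Dice above 0.95 indicates near-perfect overlap; the 4x4 cell size is the
# operating point balancing shape detail against dimensionality.
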