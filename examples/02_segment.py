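"""Segment one phantom with all three strategies and compare masks.

The fully-automated (FA) path finds its own seed; the semi-automated paths
grow from a (simulated) freehand outline or from the largest axis-aligned
rectangle (LAR) inscribed in it.
"""

import numpy as np
from skimage.measure import find_contours

from sonoskin import (PhantomSpec, dice, generate_phantom, segment_fa,
                      segment_sa)

sample = generate_phantom(PhantomSpec(), "nevus", seed=11)

# simulate a slightly sloppy freehand outline: the truth contour, coarsely
# subsampled and jittered
contour = max(find_contours(sample.truth_mask.astype(float), 0.5), key=len)
rng = np.random.default_rng(0)
outline = contour[::12] + rng.normal(0, 1.0, contour[::12].shape)

fa = segment_fa(sample.image)
freehand = segment_sa(sample.image, outline, mode="freehand")
lar = segment_sa(sample.image, outline, mode="lar")

for name, mask in [("FA", fa), ("SA freehand", freehand), ("SA LAR", lar)]:
    print(f"{name:12s} area {int(mask.sum()):4d} px, "
          f"Dice vs truth {dice(mask, sample.truth_mask):.3f}, "
          f"Dice vs freehand {dice(mask, freehand):.3f}")

# All three should agree closely on an easy nevus; the published success
# criterion for the FA path is Dice > 0.10 against the freehand reference.
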