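"""Contrast-limit a DWI-like slice with CLAHE and measure what changed.

Clip limit 0.9 on an 8x8 tile grid — the setting used for the enhanced
segmentation arm.  The quantity that matters for the active contour is the
gradient magnitude on the lesion boundary: the edge-stopping function only
halts the front where that gradient is strong.
"""

import numpy as np
from scipy import ndimage

from radstab import ClaheParams, PhantomSpec, clahe, generate_phantom

spec = PhantomSpec(lesion_intensity=0.55, background_intensity=0.35,
                   texture_amplitude=0.08, seed=3)
image, mask = generate_phantom(spec)
enhanced = clahe(image, ClaheParams(clip_limit=0.9, n_tiles=(8, 8)))

boundary = ndimage.binary_dilation(mask, iterations=1) \
    & ~ndimage.binary_erosion(mask, iterations=1)

def gradient_stats(img):
    gy, gx = np.gradient(ndimage.gaussian_filter(img, 1.5))
    g = np.hypot(gx, gy)
    return g[boundary].mean(), g[~mask & ~boundary].mean()

for name, img in (("input", image), ("CLAHE", enhanced)):
    edge, bg = gradient_stats(img)
    print(f"{name:6s} range [{img.min():.3f}, {img.max():.3f}], "
          f"boundary |grad| {edge:.4f}, background |grad| {bg:.4f}")
# CLAHE more than doubles the boundary gradient here, at the cost of also
# amplifying background noise gradients — which is exactly why the clip
# limit exists: CL -> 0 would suppress the amplification entirely
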