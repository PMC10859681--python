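"""Segment a phantom lesion three ways and compare against ground truth.

The manual arm is the (here: exact) reference delineation; the
semi-automated arm seeds region growing at the lesion centroid and refines
with a 100-iteration geodesic active contour; the enhanced arm runs the
same contour on the CLAHE image.
"""

import numpy as np

from radstab import (
    PhantomSpec, SnakeParams, clahe, dice, evolve_level_set,
    generate_phantom, region_grow,
)

spec = PhantomSpec(lesion_intensity=0.7, background_intensity=0.25,
                   noise_sigma=0.04, texture_amplitude=0.05, seed=8)
image, gt = generate_phantom(spec)
seed_pt = tuple(int(round(c)) for c in np.argwhere(gt).mean(axis=0))

grown = region_grow(image, seed_pt, tol=0.15)
acm = evolve_level_set(image, grown, SnakeParams(iterations=100, balloon=0.5))

# equalization stretches the intensity scale, so the growth tolerance is
# wider on the enhanced image
enhanced = clahe(image)
grown_e = region_grow(enhanced, seed_pt, tol=0.3)
acm_e = evolve_level_set(enhanced, grown_e, SnakeParams(iterations=100,
                                                        balloon=0.5))

print(f"ground-truth lesion area: {int(gt.sum())} px")
print(f"region growing         Dice {dice(grown, gt):.3f}")
print(f"active contour         Dice {dice(acm, gt):.3f}")
print(f"CLAHE + active contour Dice {dice(acm_e, gt):.3f}")
# Dice near 1 means the contour locked onto the true boundary.  On this
# already well-contrasted phantom the raw contour wins: CLAHE also
# amplifies intra-lesion texture, which the region grower then undergrows
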