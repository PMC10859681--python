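"""Generate a synthetic DWI-like cohort and write it to disk.

Each subject is an axial slice with a bright elliptical lesion of random
size, orientation, brightness and internal texture on a darker background,
with Rician noise and a smooth bias field — the study conditions every
other stage of the package is exercised on.
"""

import numpy as np

from radstab import default_cohort_spec, generate_cohort, write_cohort

base, variation = default_cohort_spec()
cohort = generate_cohort(10, base, variation, seed=42)

manifest = write_cohort("scratch/example_cohort", cohort)
areas = [int(mask.sum()) for _, mask in cohort]
means = [float(img[mask].mean()) for img, mask in cohort]

print(f"wrote {len(cohort)} subjects, manifest at {manifest}")
print(f"lesion areas (px):   min {min(areas)}, max {max(areas)}")
print(f"lesion mean signal:  {np.min(means):.3f} .. {np.max(means):.3f}")
# the spread in area and signal is the between-subject variance the
# downstream ICC analysis needs to detect against measurement noise
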