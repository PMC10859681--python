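"""Measure feature reproducibility with two-way-ANOVA ICC.

Simulates one observer delineating 20 lesions twice with 1.5 px boundary
jitter, extracts the feature registry per delineation, and computes the
agreement ICC per feature with its reproducibility bin.
"""

import numpy as np

from radstab import (
    FEATURE_REGISTRY, ObserverModel, categorize_icc, default_cohort_spec,
    extract_all, generate_cohort, icc_agreement, simulate_observer,
)

base, variation = default_cohort_spec()
cohort = generate_cohort(20, base, variation, seed=7)

values = {name: np.empty((20, 2)) for name in FEATURE_REGISTRY}
for subject, (image, gt_mask) in enumerate(cohort):
    for session in range(2):
        model = ObserverModel(boundary_jitter_sigma=1.5,
                              seed=1000 * subject + session)
        mask = simulate_observer(gt_mask, model)
        for name, v in extract_all(image, mask).items():
            values[name][subject, session] = v

iccs = {name: icc_agreement(table).value for name, table in values.items()}
print(f"{'feature':36s} {'ICC(A,1)':>9s}  bin")
for name in ("shape_area", "shape_perimeter", "fo_mean", "fo_entropy",
             "glcm_contrast", "glcm_correlation"):
    print(f"{name:36s} {iccs[name]:9.3f}  {categorize_icc(min(iccs[name], 1))}")
mean = np.mean(list(iccs.values()))
sd = np.std(list(iccs.values()))
print(f"\nmean ICC over {len(iccs)} features: {mean:.3f} +/- {sd:.3f}")
# shape features tolerate boundary jitter far better than texture features,
# whose range-relative quantization shifts when background pixels leak in
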