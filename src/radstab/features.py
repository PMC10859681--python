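"""Radiomics feature registry: GLCM texture, first-order statistics, shape.

The registry holds exactly 36 named features — 21 Haralick-family features
of the gray-level co-occurrence matrix (GLCM), 6 first-order intensity
statistics, and 9 shape descriptors of the lesion mask — extracted from one
(image, mask) pair.  Two inverse-difference variants are kept under the
homogeneity heading: ``glcm_homogeneity1`` (inverse difference,
sum P/(1+|i-j|)) and ``glcm_homogeneity2`` (inverse difference moment,
sum P/(1+(i-j)^2)).

Conventions, chosen once and fixed so that every value is finite on every
valid input:

* GLCM gray levels are weighted 1..N in the feature formulas; logarithms are
  base 2 with 0*log(0) = 0.
* GLCM correlation of a zero-variance matrix is 1 (a constant region is
  perfectly correlated with itself); the information measures fall back to 0
  when their normalizers vanish.
* Quantization is range-relative over the masked region (equal-width bins
  spanning [min, max]); a constant region maps to level 0.  Adding a
  constant to the image therefore leaves all GLCM features unchanged.
* First-order variance/skewness/kurtosis use population moments (divisor n);
  kurtosis is not excess-corrected; skewness and kurtosis of a
  zero-variance region are 0 by convention.
* Shape orientation is reported in degrees in (-90, 90], measured from the
  row axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

GLCM_FEATURES = (
    "glcm_correlation",
    "glcm_contrast",
    "glcm_autocorrelation",
    "glcm_difference_variance",
    "glcm_homogeneity1",
    "glcm_dissimilarity",
    "glcm_entropy",
    "glcm_energy",
    "glcm_homogeneity2",
    "glcm_cluster_shade",
    "glcm_maximum_probability",
    "glcm_sum_variance",
    "glcm_sum_of_squares",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_cluster_prominence",
    "glcm_imc2",
    "glcm_imc1",
    "glcm_difference_entropy",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment_normalized",
)

FIRST_ORDER_FEATURES = (
    "fo_entropy",
    "fo_kurtosis",
    "fo_skewness",
    "fo_energy",
    "fo_variance",
    "fo_mean",
)

SHAPE_FEATURES = (
    "shape_area",
    "shape_major_axis_length",
    "shape_minor_axis_length",
    "shape_perimeter",
    "shape_equiv_diameter",
    "shape_convex_area",
    "shape_orientation",
    "shape_solidity",
    "shape_eccentricity",
)

FEATURE_REGISTRY = GLCM_FEATURES + FIRST_ORDER_FEATURES + SHAPE_FEATURES

FEATURE_GROUPS = {
    **{name: "glcm" for name in GLCM_FEATURES},
    **{name: "first_order" for name in FIRST_ORDER_FEATURES},
    **{name: "shape" for name in SHAPE_FEATURES},
}

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings: GLCM quantization levels and pixel distance,
    angles to average, and the first-order entropy histogram bin count."""

    glcm_levels: int = 8
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    first_order_bins: int = 64

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        for a in self.glcm_angles:
            if a not in _ANGLE_OFFSETS:
                raise ValueError(f"angle {a} not in {sorted(_ANGLE_OFFSETS)}")
        if self.first_order_bins < 2:
            raise ValueError("first_order_bins must be >= 2")


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Bin masked intensities into ``n_levels`` equal-width levels over the
    masked [min, max] range; constant regions map to level 0.  Pixels outside
    the mask are set to level 0 and must be ignored by consumers."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(image.shape, dtype=np.intp)
    if hi > lo:
        levels = ((image - lo) / (hi - lo) * n_levels).astype(np.intp)
        out[mask] = np.clip(levels[mask], 0, n_levels - 1)
    return out


def glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    distance: int = 1,
    angle: int = 0,
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Counts pairs of levels at the (distance, angle) offset with both pixels
    inside the mask, accumulates each pair in both orders, and normalizes
    to total mass 1.  Raises if the offset yields no valid pair.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    mask = np.asarray(mask, dtype=bool)
    q = np.asarray(quantized)
    dr, dc = (distance * o for o in _ANGLE_OFFSETS[angle])
    h, w = q.shape

    rows, cols = np.nonzero(mask)
    r2, c2 = rows + dr, cols + dc
    ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
    rows, cols, r2, c2 = rows[ok], cols[ok], r2[ok], c2[ok]
    ok = mask[r2, c2]
    i, j = q[rows[ok], cols[ok]], q[r2[ok], c2[ok]]
    if i.size == 0:
        raise ValueError("no valid pixel pairs for this offset")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)
    return counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 21 registry features of a normalized GLCM (1-based level weights)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"GLCM must be square, got shape {P.shape}")
    if abs(P.sum() - 1.0) > 1e-8 or (P < 0).any():
        raise ValueError("GLCM must be normalized (non-negative, sum 1)")
    n = P.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # distributions of i+j (2..2n) and |i-j| (0..n-1)
    ks = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.zeros(2 * n - 1)
    kd = np.arange(0, n, dtype=float)
    p_diff = np.zeros(n)
    for a in range(n):
        for b in range(n):
            p_sum[a + b] += P[a, b]
            p_diff[abs(a - b)] += P[a, b]

    autocorr = float((i * j * P).sum())
    if sd_x * sd_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 1.0

    hxy = _entropy2(P.ravel())
    outer = px[:, None] * py[None, :]
    valid = (P > 0) & (outer > 0)
    hxy1 = float(-(P[valid] * np.log2(outer[valid])).sum())
    hxy2 = _entropy2(outer.ravel())
    hx, hy = _entropy2(px), _entropy2(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    sum_average = float((ks * p_sum).sum())
    diff_mean = float((kd * p_diff).sum())

    return {
        "glcm_correlation": float(correlation),
        "glcm_contrast": float(((i - j) ** 2 * P).sum()),
        "glcm_autocorrelation": autocorr,
        "glcm_difference_variance": float(((kd - diff_mean) ** 2 * p_diff).sum()),
        "glcm_homogeneity1": float((P / (1.0 + np.abs(i - j))).sum()),
        "glcm_dissimilarity": float((np.abs(i - j) * P).sum()),
        "glcm_entropy": hxy,
        "glcm_energy": float((P**2).sum()),
        "glcm_homogeneity2": float((P / (1.0 + (i - j) ** 2)).sum()),
        "glcm_cluster_shade": float(((i + j - mu_x - mu_y) ** 3 * P).sum()),
        "glcm_maximum_probability": float(P.max()),
        "glcm_sum_variance": float(((ks - sum_average) ** 2 * p_sum).sum()),
        "glcm_sum_of_squares": float(((i - mu_x) ** 2 * P).sum()),
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": _entropy2(p_sum),
        "glcm_cluster_prominence": float(((i + j - mu_x - mu_y) ** 4 * P).sum()),
        "glcm_imc2": imc2,
        "glcm_imc1": float(imc1),
        "glcm_difference_entropy": _entropy2(p_diff),
        "glcm_inverse_difference_normalized": float(
            (P / (1.0 + np.abs(i - j) / n)).sum()
        ),
        "glcm_inverse_difference_moment_normalized": float(
            (P / (1.0 + ((i - j) / n) ** 2)).sum()
        ),
    }


def first_order_features(
    image: np.ndarray, mask: np.ndarray, n_bins: int = 64
) -> dict[str, float]:
    """Six first-order statistics of the masked intensities."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(image, dtype=float)[mask]
    mean = float(v.mean())
    # constant regions short-circuit so the degenerate conventions are exact
    var = float(((v - mean) ** 2).mean()) if v.min() < v.max() else 0.0
    if var > 0:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew = m3 / var**1.5
        kurt = m4 / var**2
    else:
        skew = kurt = 0.0
    lo, hi = v.min(), v.max()
    if hi > lo:
        hist, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
        entropy = _entropy2(hist / hist.sum())
    else:
        entropy = 0.0
    return {
        "fo_entropy": entropy,
        "fo_kurtosis": kurt,
        "fo_skewness": skew,
        "fo_energy": float((v**2).sum()),
        "fo_variance": var,
        "fo_mean": mean,
    }


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Nine shape descriptors of the lesion mask (all true pixels as one
    region; ellipse descriptors from normalized second central moments)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(rp.area)
    return {
        "shape_area": area,
        "shape_major_axis_length": float(rp.axis_major_length),
        "shape_minor_axis_length": float(rp.axis_minor_length),
        "shape_perimeter": float(rp.perimeter),
        "shape_equiv_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "shape_convex_area": float(rp.area_convex),
        "shape_orientation": float(np.rad2deg(rp.orientation)),
        "shape_solidity": float(rp.solidity),
        "shape_eccentricity": float(rp.eccentricity),
    }


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Extract the full 36-feature registry vector for one (image, mask) pair.

    GLCM features are computed per angle at the configured distance and
    averaged over the angles.  The returned dict has exactly the registry's
    names in registry order and contains no NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    q = quantize(image, mask, config.glcm_levels)
    per_angle = []
    for angle in config.glcm_angles:
        P = glcm(q, mask, config.glcm_levels, config.glcm_distance, angle)
        per_angle.append(glcm_features(P))
    glcm_avg = {
        name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_FEATURES
    }
    out = {**glcm_avg,
           **first_order_features(image, mask, config.first_order_bins),
           **shape_features(mask)}
    vector = {name: out[name] for name in FEATURE_REGISTRY}
    bad = [k for k, v in vector.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return vector


def registry_manifest() -> list[dict[str, str]]:
    """Machine-readable registry listing (name, group) in fixed order."""
    return [{"name": n, "group": FEATURE_GROUPS[n]} for n in FEATURE_REGISTRY]
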