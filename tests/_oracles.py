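"""Independent reference implementations used only to check the package.

Everything here is deliberately written in plain Python loops, straight from
textbook definitions, sharing no code path with the implementation under
test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def glcm_pairs_oracle(quantized, mask, n_levels, distance, angle):
    """Exhaustive pair enumeration GLCM (symmetric, normalized)."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[angle]
    dr, dc = dr * distance, dc * distance
    h, w = quantized.shape
    counts = [[0.0] * n_levels for _ in range(n_levels)]
    total = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                i, j = int(quantized[r, c]), int(quantized[r2, c2])
                counts[i][j] += 1
                counts[j][i] += 1
                total += 2
    if total == 0:
        raise ValueError("no pairs")
    return np.array(counts) / total


def _log2(x):
    return math.log(x, 2)


def glcm_features_oracle(P):
    """Haralick-family features from textbook formulas, loop-coded.

    Levels are weighted 1..N; logs base 2 with 0*log 0 = 0; correlation of a
    zero-variance matrix is 1; information measures fall back to 0 when
    their normalizers vanish.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum((i + 1) * px[i] for i in range(n))
    mu_y = sum((j + 1) * py[j] for j in range(n))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(n)))

    p_sum = [0.0] * (2 * n - 1)   # index s -> i+j = s+2 (1-based levels)
    p_diff = [0.0] * n            # index d -> |i-j| = d
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    out = {}
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(n) for j in range(n)
    )
    out["glcm_contrast"] = sum(
        (i - j) ** 2 * P[i][j] for i in range(n) for j in range(n)
    )
    if sd_x * sd_y > 0:
        out["glcm_correlation"] = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * P[i][j]
            for i in range(n) for j in range(n)
        ) / (sd_x * sd_y)
    else:
        out["glcm_correlation"] = 1.0
    dmean = sum(d * p_diff[d] for d in range(n))
    out["glcm_difference_variance"] = sum(
        (d - dmean) ** 2 * p_diff[d] for d in range(n)
    )
    out["glcm_homogeneity1"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
    )
    out["glcm_dissimilarity"] = sum(
        abs(i - j) * P[i][j] for i in range(n) for j in range(n)
    )
    hxy = -sum(
        P[i][j] * _log2(P[i][j])
        for i in range(n) for j in range(n) if P[i][j] > 0
    )
    out["glcm_entropy"] = hxy
    out["glcm_energy"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    out["glcm_homogeneity2"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
    )
    out["glcm_cluster_shade"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 3 * P[i][j]
        for i in range(n) for j in range(n)
    )
    out["glcm_maximum_probability"] = max(
        P[i][j] for i in range(n) for j in range(n)
    )
    smean = sum((s + 2) * p_sum[s] for s in range(2 * n - 1))
    out["glcm_sum_average"] = smean
    out["glcm_sum_variance"] = sum(
        (s + 2 - smean) ** 2 * p_sum[s] for s in range(2 * n - 1)
    )
    out["glcm_sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * P[i][j] for i in range(n) for j in range(n)
    )
    out["glcm_sum_entropy"] = -sum(
        p_sum[s] * _log2(p_sum[s]) for s in range(2 * n - 1) if p_sum[s] > 0
    )
    out["glcm_cluster_prominence"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i][j]
        for i in range(n) for j in range(n)
    )
    hx = -sum(p * _log2(p) for p in px if p > 0)
    hy = -sum(p * _log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i][j] * _log2(px[i] * py[j])
        for i in range(n) for j in range(n)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(n) for j in range(n)
        if px[i] * py[j] > 0
    )
    out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0)))
    out["glcm_difference_entropy"] = -sum(
        p_diff[d] * _log2(p_diff[d]) for d in range(n) if p_diff[d] > 0
    )
    out["glcm_inverse_difference_normalized"] = sum(
        P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
    )
    out["glcm_inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / n**2) for i in range(n) for j in range(n)
    )
    return out


def first_order_oracle(values, n_bins):
    """Direct-formula first-order statistics of a 1-D sample."""
    v = list(map(float, values))
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    if var > 0:
        skew = (sum((x - mean) ** 3 for x in v) / n) / var**1.5
        kurt = (sum((x - mean) ** 4 for x in v) / n) / var**2
    else:
        skew = kurt = 0.0
    lo, hi = min(v), max(v)
    entropy = 0.0
    if hi > lo:
        counts = [0] * n_bins
        for x in v:
            b = int((x - lo) / (hi - lo) * n_bins)
            counts[min(b, n_bins - 1)] += 1
        for c in counts:
            if c:
                entropy -= (c / n) * _log2(c / n)
    return {
        "fo_entropy": entropy,
        "fo_kurtosis": kurt,
        "fo_skewness": skew,
        "fo_energy": sum(x * x for x in v),
        "fo_variance": var,
        "fo_mean": mean,
    }


def anova_oracle(table):
    """Brute-force two-way sums-of-squares decomposition."""
    t = [[float(x) for x in row] for row in np.asarray(table)]
    n, k = len(t), len(t[0])
    grand = sum(sum(row) for row in t) / (n * k)
    rmeans = [sum(row) / k for row in t]
    cmeans = [sum(t[i][j] for i in range(n)) / n for j in range(k)]
    ss_r = k * sum((m - grand) ** 2 for m in rmeans)
    ss_c = n * sum((m - grand) ** 2 for m in cmeans)
    ss_e = sum(
        (t[i][j] - rmeans[i] - cmeans[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    ss_w = sum(
        (t[i][j] - rmeans[i]) ** 2 for i in range(n) for j in range(k)
    )
    return {
        "ms_rows": ss_r / (n - 1),
        "ms_cols": ss_c / (k - 1),
        "ms_error": ss_e / ((n - 1) * (k - 1)),
        "ms_within": ss_w / (n * (k - 1)),
    }


def icc_oracle(table):
    """Moment-based ICC(A,1) and ICC(C,1) from the SS decomposition."""
    t = np.asarray(table, dtype=float)
    n, k = t.shape
    ms = anova_oracle(t)
    msr, msc, mse = ms["ms_rows"], ms["ms_cols"], ms["ms_error"]
    a1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    c1 = (msr - mse) / (msr + (k - 1) * mse)
    return a1, c1


def histogram_equalize_oracle(image, n_bins):
    """Brute-force global histogram equalization: each pixel maps to the
    fraction of pixels whose bin is <= its own bin."""
    img = np.asarray(image, dtype=float)
    flat = img.ravel()
    bins = [min(int(v * n_bins), n_bins - 1) for v in flat]
    out = np.empty(flat.size)
    total = flat.size
    counts = [0] * n_bins
    for b in bins:
        counts[b] += 1
    cum = []
    run = 0
    for c in counts:
        run += c
        cum.append(run / total)
    for idx, b in enumerate(bins):
        out[idx] = cum[b]
    return out.reshape(img.shape)


def clip_redistribute_oracle(hist, ceiling, max_rounds=10000):
    """Iterative clip-and-redistribute until residual excess < 1 count."""
    h = [float(x) for x in hist]
    for _ in range(max_rounds):
        excess = sum(max(x - ceiling, 0.0) for x in h)
        if excess == 0:
            break
        h = [min(x, ceiling) + excess / len(h) for x in h]
        if sum(max(x - ceiling, 0.0) for x in h) < 1.0:
            break
    return np.array(h)


def flood_fill_oracle(image, seed, tol):
    """BFS 4-connected flood fill within tol of the seed intensity."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    ref = img[seed]
    mask = np.zeros((h, w), dtype=bool)
    queue = deque([seed])
    mask[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and not mask[r2, c2]:
                if abs(img[r2, c2] - ref) <= tol:
                    mask[r2, c2] = True
                    queue.append((r2, c2))
    return mask


def random_measurement_table(rng, n=None, k=None):
    """A random complete n x k table with row, column and noise effects."""
    n = n or int(rng.integers(2, 21))
    k = k or int(rng.integers(2, 5))
    subj = rng.normal(0, rng.uniform(0.5, 3.0), size=(n, 1))
    rater = rng.normal(0, rng.uniform(0.0, 1.0), size=(1, k))
    noise = rng.normal(0, rng.uniform(0.05, 1.0), size=(n, k))
    return subj + rater + noise
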