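"""Shared grid helpers."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, negative inside."""
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / s
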