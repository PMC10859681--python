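"""Contrast-limited adaptive histogram equalization (CLAHE), from scratch.

The image is partitioned into a grid of tiles; each tile's intensity
histogram is clipped at a ceiling controlled by the clip limit CL, the
clipped-off mass is redistributed uniformly over all bins, and the tile's
equalization transfer function is taken from the cumulative distribution of
the clipped histogram.  Pixel values are mapped by bilinear interpolation
between the transfer functions of the four surrounding tile centers (clamped
at the image edges), which removes tile-seam artifacts.

CL semantics: the per-bin count ceiling is ``max(CL * tile_pixels,
tile_pixels / n_bins)`` — CL is the maximum fraction of a tile's pixels a
single bin may hold.  CL = 1 never clips (plain adaptive equalization);
CL -> 0 clips to the uniform histogram, whose transfer function is the
identity, so the image passes through almost unchanged.  The lower bound at
the uniform height makes every CL in (0, 1] well defined.

A tile whose histogram is concentrated in a single bin carries no contrast
information; its transfer function is defined as the identity, which makes
constant images exact fixed points of the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE hyperparameters: clip limit CL in (0, 1], tile grid NT, bins."""

    clip_limit: float = 0.9
    n_tiles: tuple[int, int] = (8, 8)
    n_bins: int = 256

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError(f"clip limit must be in (0, 1], got {self.clip_limit}")
        if self.n_tiles[0] < 1 or self.n_tiles[1] < 1:
            raise ValueError(f"tile grid must be >= 1x1, got {self.n_tiles}")
        if self.n_bins < 2:
            raise ValueError(f"need at least 2 histogram bins, got {self.n_bins}")


def clip_histogram(
    hist: np.ndarray, clip_limit: float, *, iterative: bool = False
) -> np.ndarray:
    """Clip a tile histogram at the CL ceiling and redistribute the excess.

    The ceiling is ``max(clip_limit * sum(hist), sum(hist) / n_bins)`` counts
    per bin.  Excess mass is spread uniformly over all bins (one pass by
    default; with ``iterative=True`` redistribution repeats until the residual
    excess above the ceiling is below one count).  Total mass is conserved
    exactly in both modes.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip limit must be > 0, got {clip_limit}")
    hist = np.asarray(hist, dtype=float)
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        return hist.copy()
    ceiling = max(clip_limit * total, total / hist.size)
    out = hist.copy()
    while True:
        excess = np.maximum(out - ceiling, 0.0)
        if excess.sum() == 0:
            break
        out = np.minimum(out, ceiling) + excess.sum() / out.size
        if not iterative or np.maximum(out - ceiling, 0.0).sum() < 1.0:
            break
    return out


def _tile_slices(n: int, tiles: int) -> list[slice]:
    edges = np.linspace(0, n, tiles + 1).round().astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(tiles)]


def clahe(image: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Apply CLAHE to a grayscale image with intensities in [0, 1].

    Deterministic; output lies in [0, 1]; constant images are fixed points.
    Raises if the image has fewer rows/columns than the tile grid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    tr, tc = params.n_tiles
    h, w = image.shape
    if h < tr or w < tc:
        raise ValueError(
            f"image {h}x{w} is smaller than the {tr}x{tc} tile grid"
        )

    nb = params.n_bins
    bins = np.clip((image * nb).astype(int), 0, nb - 1)

    row_sl = _tile_slices(h, tr)
    col_sl = _tile_slices(w, tc)
    luts = np.empty((tr, tc, nb))
    degenerate = np.zeros((tr, tc), dtype=bool)
    centers_r = np.array([(s.start + s.stop - 1) / 2.0 for s in row_sl])
    centers_c = np.array([(s.start + s.stop - 1) / 2.0 for s in col_sl])

    for i, rs in enumerate(row_sl):
        for j, cs in enumerate(col_sl):
            tile_bins = bins[rs, cs]
            hist = np.bincount(tile_bins.ravel(), minlength=nb).astype(float)
            if np.count_nonzero(hist) <= 1:
                degenerate[i, j] = True
                luts[i, j] = (np.arange(nb) + 0.5) / nb  # placeholder, unused
                continue
            clipped = clip_histogram(hist, params.clip_limit, iterative=True)
            luts[i, j] = np.cumsum(clipped) / clipped.sum()

    # fractional tile coordinates of every pixel, clamped beyond edge centers
    fr = np.interp(np.arange(h), centers_r, np.arange(tr)) if tr > 1 else np.zeros(h)
    fc = np.interp(np.arange(w), centers_c, np.arange(tc)) if tc > 1 else np.zeros(w)
    i0 = np.minimum(np.floor(fr).astype(int), tr - 1)
    j0 = np.minimum(np.floor(fc).astype(int), tc - 1)
    wr = (fr - i0)[:, None]
    wc = (fc - j0)[None, :]
    i1 = np.minimum(i0 + 1, tr - 1)
    j1 = np.minimum(j0 + 1, tc - 1)

    # blend the four tile mappings as offsets from the input so that
    # degenerate (identity) tiles contribute exactly zero: constant images
    # are then bit-exact fixed points
    out = image.copy()
    corners = [
        (i0, j0, (1 - wr) * (1 - wc)),
        (i0, j1, (1 - wr) * wc),
        (i1, j0, wr * (1 - wc)),
        (i1, j1, wr * wc),
    ]
    for ti, tj, weight in corners:
        tile_i = np.broadcast_to(ti[:, None], image.shape)
        tile_j = np.broadcast_to(tj[None, :], image.shape)
        mapped = luts[tile_i, tile_j, bins]
        delta = np.where(degenerate[tile_i, tile_j], 0.0, mapped - image)
        out += weight * delta
    return np.clip(out, 0.0, 1.0)


def histogram_equalize(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Plain global histogram equalization (the CL=1, NT=(1,1) degenerate
    case), exposed for testing and comparison."""
    return clahe(image, ClaheParams(clip_limit=1.0, n_tiles=(1, 1), n_bins=n_bins))
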