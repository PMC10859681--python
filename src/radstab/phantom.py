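"""Synthetic DWI-like phantom generation.

Axial diffusion-weighted slices of a pelvic lesion are emulated as a bright
elliptical region (restricted diffusion) on a darker background, corrupted by
a smooth multiplicative bias field (coil inhomogeneity) and Rician noise (the
magnitude-MRI noise model, Rayleigh at zero signal).  Repeat manual
delineations by human observers are emulated by a smooth angular boundary
jitter applied to the ground-truth mask.

All outputs are pure functions of their parameter objects, including the
embedded RNG seeds, so every downstream stage of the pipeline is testable
without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
from scipy import ndimage

from ._util import signed_distance as _signed_distance


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion slice.

    Intensities are normalized to [0, 1].  ``noise_sigma`` is the scale of
    the two Gaussian quadrature components of the Rician noise,
    ``bias_amplitude`` the peak-to-peak fraction of the multiplicative
    inhomogeneity field, and ``texture_amplitude``/``texture_scale`` control
    a smooth intra-lesion heterogeneity field (amplitude in intensity units,
    correlation length in pixels) that gives each subject's lesion its own
    texture.
    """

    height: int = 128
    width: int = 128
    lesion_center: tuple[float, float] = (64.0, 64.0)
    lesion_axes: tuple[float, float] = (30.0, 20.0)
    lesion_rotation: float = 0.0  # degrees
    lesion_intensity: float = 0.8
    background_intensity: float = 0.25
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.2
    texture_amplitude: float = 0.0
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_intensity < self.lesion_intensity <= 1.0):
            raise ValueError(
                "need 0 <= background_intensity < lesion_intensity <= 1, got "
                f"{self.background_intensity} / {self.lesion_intensity}"
            )
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        if self.texture_amplitude < 0 or self.texture_scale <= 0:
            raise ValueError("texture_amplitude must be >= 0 and texture_scale > 0")
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ValueError("lesion semi-axes must be positive")
        r, c = self.lesion_center
        reach = max(a, b)
        if (r - reach < 0 or r + reach > self.height - 1
                or c - reach < 0 or c + reach > self.width - 1):
            raise ValueError(
                f"lesion (center {self.lesion_center}, axes {self.lesion_axes}) "
                f"does not fit inside a {self.height}x{self.width} image"
            )


@dataclass(frozen=True)
class ObserverModel:
    """Smooth radial boundary jitter emulating repeat manual delineation.

    ``boundary_jitter_sigma`` is the pointwise standard deviation (pixels) of
    the radial displacement of the lesion boundary; ``smoothness`` is the
    angular correlation length (degrees of arc) of that displacement field.
    ``boundary_jitter_sigma = 0`` reproduces the input mask exactly.
    """

    boundary_jitter_sigma: float = 1.5
    smoothness: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sigma < 0:
            raise ValueError("boundary_jitter_sigma must be >= 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")


_N_ANGLES = 64  # angular sampling of the jitter displacement field


def _ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    r0, c0 = spec.lesion_center
    theta = np.deg2rad(spec.lesion_rotation)
    dr, dc = rows - r0, cols - c0
    # rotate into the ellipse frame; axis a lies along the rotated row axis
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    a, b = spec.lesion_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    """Low-order polynomial surface, normalized to 1 +/- bias_amplitude/2."""
    if spec.bias_amplitude == 0:
        return np.ones((spec.height, spec.width))
    y = np.linspace(-1.0, 1.0, spec.height)[:, None]
    x = np.linspace(-1.0, 1.0, spec.width)[None, :]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB1A5]))
    c = rng.standard_normal(5)
    surf = c[0] * y + c[1] * x + c[2] * y * x + c[3] * (y**2 - 0.5) + c[4] * (x**2 - 0.5)
    lo, hi = surf.min(), surf.max()
    if hi - lo < 1e-12:
        return np.ones((spec.height, spec.width))
    surf = (surf - lo) / (hi - lo) - 0.5  # in [-1/2, 1/2]
    return 1.0 + spec.bias_amplitude * surf


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one DWI-like slice and its ground-truth lesion mask.

    The image is ``bias_field * piecewise_intensity`` with Rician noise
    sqrt((s + g1)^2 + g2^2), g1, g2 ~ N(0, noise_sigma^2) independent,
    clipped to [0, 1].  Identical spec (including seed) gives bit-identical
    output.

    Returns
    -------
    image : float64 array in [0, 1]
    mask : bool array, the rasterized lesion ellipse
    """
    mask = _ellipse_mask(spec)
    signal = np.where(mask, spec.lesion_intensity, spec.background_intensity)
    if spec.texture_amplitude > 0:
        # subject-specific intra-lesion heterogeneity: a smooth correlated
        # random field (unit pointwise std) added inside the lesion
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E47]))
        white = rng.standard_normal(signal.shape)
        smooth = ndimage.gaussian_filter(white, spec.texture_scale)
        smooth /= smooth.std()
        signal = np.where(mask, signal + spec.texture_amplitude * smooth, signal)
    signal = signal * _bias_field(spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x401E]))
        g1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        g2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.hypot(signal + g1, g2)
    return np.clip(signal, 0.0, 1.0), mask


def simulate_observer(mask: np.ndarray, model: ObserverModel) -> np.ndarray:
    """Perturb a lesion mask the way a repeat manual delineation would.

    A zero-mean Gaussian displacement field is sampled on 64 equally spaced
    polar angles about the mask centroid, smoothed with a periodic Gaussian
    kernel of width ``model.smoothness`` degrees, renormalized to pointwise
    std ``boundary_jitter_sigma``, and applied as an offset to the signed
    distance from the boundary: a pixel at angle theta belongs to the
    perturbed mask iff signed_dist(pixel) < delta(theta).  With
    ``boundary_jitter_sigma = 0`` the input mask is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if model.boundary_jitter_sigma == 0:
        return mask.copy()

    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0x0B5E]))
    raw = rng.standard_normal(_N_ANGLES)
    # periodic Gaussian smoothing, kernel width in angular samples
    width = model.smoothness / (360.0 / _N_ANGLES)
    k = np.arange(_N_ANGLES)
    d = np.minimum(k, _N_ANGLES - k).astype(float)
    kernel = np.exp(-0.5 * (d / width) ** 2)
    kernel /= np.linalg.norm(kernel)  # unit l2 norm keeps pointwise std = sigma
    delta = model.boundary_jitter_sigma * np.real(
        np.fft.ifft(np.fft.fft(raw) * np.fft.fft(kernel))
    )

    r0, c0 = ndimage.center_of_mass(mask)
    rows, cols = np.mgrid[0:mask.shape[0], 0:mask.shape[1]].astype(float)
    theta = np.arctan2(rows - r0, cols - c0)  # (-pi, pi]
    pos = (theta + np.pi) / (2 * np.pi) * _N_ANGLES
    i0 = np.floor(pos).astype(int) % _N_ANGLES
    i1 = (i0 + 1) % _N_ANGLES
    frac = pos - np.floor(pos)
    delta_field = (1 - frac) * delta[i0] + frac * delta[i1]

    out = _signed_distance(mask) < delta_field
    if not out.any():  # jitter collapsed the lesion; keep at least the core
        out = _signed_distance(mask) < float(delta_field.min()) + 1.0
        if not out.any():
            out = mask.copy()
    return out


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    variation: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate a cohort of phantoms with per-subject parameter variation.

    ``variation`` maps PhantomSpec field names to (min, max) ranges sampled
    uniformly per subject; tuple-valued fields (``lesion_axes``,
    ``lesion_center``) draw one value per component from the same range.
    At least two subjects are required (a reliability analysis downstream
    needs between-subject variance).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    variation = dict(variation or {})
    valid = {f.name for f in fields(PhantomSpec)}
    for key, (lo, hi) in variation.items():
        if key not in valid:
            raise KeyError(f"unknown PhantomSpec field {key!r}")
        if lo > hi:
            raise ValueError(f"degenerate range for {key!r}: min {lo} > max {hi}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0407]))
    cohort = []
    for i in range(n_subjects):
        overrides: dict = {"seed": int(rng.integers(0, 2**31 - 1))}
        for key, (lo, hi) in variation.items():
            current = getattr(base_spec, key)
            if isinstance(current, tuple):
                overrides[key] = tuple(float(rng.uniform(lo, hi)) for _ in current)
            else:
                overrides[key] = float(rng.uniform(lo, hi))
        cohort.append(generate_phantom(replace(base_spec, **overrides)))
    return cohort


def default_cohort_spec() -> tuple[PhantomSpec, dict[str, tuple[float, float]]]:
    """Study-like cohort conditions: 128 px axial slices, lesions of varying
    size (semi-axes 12-30 px), brightness (0.6-0.95), orientation and
    intra-lesion texture (heterogeneity amplitude 0.03-0.15 at correlation
    length 2-6 px), on a 0.25 background with 3% Rician noise and 20% bias —
    a desk-scale stand-in for the variability of a clinical DWI series."""
    base = PhantomSpec()
    variation = {
        "lesion_axes": (12.0, 30.0),
        "lesion_rotation": (0.0, 180.0),
        "lesion_intensity": (0.6, 0.95),
        "texture_amplitude": (0.03, 0.15),
        "texture_scale": (2.0, 6.0),
    }
    return base, variation
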