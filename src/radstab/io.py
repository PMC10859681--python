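"""Reading and writing grayscale images and masks (PNG, NIfTI, DICOM).

All images enter the pipeline as float64 arrays with intensities in [0, 1]:
integer PNGs are divided by their bit-depth maximum, NIfTI and DICOM data
have their stored slope/intercept applied (by nibabel/pydicom) and are then
min-max rescaled only if they fall outside [0, 1].  DICOM is read-only.
"""

from __future__ import annotations

import csv
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .phantom import PhantomSpec


def _rescale_unit(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    lo, hi = data.min(), data.max()
    if lo >= 0.0 and hi <= 1.0:
        return data
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def read_image(path) -> np.ndarray:
    """Read a 2-D grayscale image as float64 in [0, 1].

    Supports 8/16-bit grayscale PNG, NIfTI (.nii/.nii.gz, slope/intercept
    applied), and single-frame grayscale DICOM (.dcm, rescale slope and
    intercept applied).  Color or multi-frame input is rejected.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.squeeze(nib.load(path).get_fdata())
        if data.ndim != 2:
            raise ValueError(f"unsupported NIfTI: expected one slice, got {data.shape}")
        return _rescale_unit(data)
    if name.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) != 1:
            raise ValueError("unsupported DICOM: multi-frame input")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise ValueError("unsupported DICOM: color input")
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        return _rescale_unit(arr * slope + inter)

    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image: expected grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return _rescale_unit(arr)


def write_image(image: np.ndarray, path, *, bit_depth: int = 16) -> None:
    """Write a [0, 1] grayscale image as 8/16-bit PNG or float32 NIfTI."""
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), path)
        return
    import imageio.v3 as iio

    if bit_depth == 8:
        iio.imwrite(path, np.round(image * 255).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(path, np.round(image * 65535).astype(np.uint16))
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as 0/255 PNG or 0/1 NIfTI."""
    mask = np.asarray(mask, dtype=bool)
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)
        return
    import imageio.v3 as iio

    iio.imwrite(path, (mask * np.uint8(255)))


def write_cohort(
    out_dir,
    cohort: list[tuple[np.ndarray, np.ndarray]],
    specs: list[PhantomSpec] | None = None,
    fmt: str = "png",
) -> Path:
    """Write a phantom cohort (images, masks, manifest CSV); returns the
    manifest path.  The manifest lists subject_id, image/mask paths and, if
    given, the generating spec parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"png": ".png", "nifti": ".nii.gz"}[fmt]
    manifest = out_dir / "manifest.csv"
    spec_fields = list(asdict(specs[0])) if specs else []
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "image_path", "mask_path", *spec_fields])
        for i, (image, mask) in enumerate(cohort):
            img_path = out_dir / f"subject_{i:03d}_image{ext}"
            msk_path = out_dir / f"subject_{i:03d}_mask{ext}"
            write_image(image, img_path)
            write_mask(mask, msk_path)
            extra = [asdict(specs[i])[f] for f in spec_fields] if specs else []
            writer.writerow([i, img_path.name, msk_path.name, *extra])
    return manifest
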