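"""Image and manifest I/O plus the intensity-normalization contract.

Stored images are 8-bit grayscale (PNG) or single-slice NIfTI volumes;
network tensors live in [-1, 1].  All quality metrics are computed in the
uint8 domain so the 255-peak PSNR convention and the 8-bit FSIM constants
apply; :func:`normalize` / :func:`denormalize` are the only crossing
points between the two domains.

Coordinate convention: row-major, origin top-left.  NIfTI volumes with a
singleton third axis are squeezed to 2D without any axis flips.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

#: ITU-R BT.601 luma weights used when an RGB PNG must be collapsed to gray
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclasses.dataclass
class ImageSlice:
    """One 2D grayscale slice with acquisition metadata."""

    pixels: np.ndarray
    intensity_domain: str = "uint8"  # "uint8" or "normalized"
    modality_name: str | None = None
    field_strength: float | None = None
    subject_id: str | None = None
    slice_index: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.intensity_domain not in ("uint8", "normalized"):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, domain: str) -> "ImageSlice":
        return dataclasses.replace(self, pixels=pixels, intensity_domain=domain)


def normalize(sl: ImageSlice) -> ImageSlice:
    """Affine map uint8 [0, 255] -> [-1, 1] (0 -> -1, 255 -> +1)."""
    if sl.intensity_domain != "uint8":
        raise ValueError("normalize expects a uint8-domain slice")
    x = sl.pixels.astype(np.float32) * (2.0 / 255.0) - 1.0
    return sl.with_pixels(x, "normalized")


def denormalize(sl: ImageSlice) -> ImageSlice:
    """Inverse affine map [-1, 1] -> uint8, rounded to integer levels."""
    if sl.intensity_domain != "normalized":
        raise ValueError("denormalize expects a normalized-domain slice")
    x = np.asarray(sl.pixels, dtype=np.float64)
    if x.min() < -1.0 - 1e-5 or x.max() > 1.0 + 1e-5:
        raise ValueError("normalized pixels must lie in [-1, 1]")
    y = np.clip(np.rint((x + 1.0) * (255.0 / 2.0)), 0, 255).astype(np.uint8)
    return sl.with_pixels(y, "uint8")


def save_slice(sl: ImageSlice, path) -> None:
    """Write a uint8 slice as PNG or NIfTI (.nii/.nii.gz), by extension."""
    if sl.intensity_domain != "uint8":
        raise ValueError("only uint8-domain slices are stored on disk")
    path = Path(path)
    data = np.ascontiguousarray(sl.pixels, dtype=np.uint8)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(data[:, :, None], affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0))
        nib.save(img, str(path))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(data, mode="L").save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_slice(path, manifest_record=None) -> ImageSlice:
    """Read a PNG or NIfTI slice; metadata is taken from the manifest record.

    Without a record the slice is still loaded (with a warning) and the
    metadata fields stay None.  RGB PNGs are collapsed to grayscale with
    BT.601 luma weights; NIfTI volumes must have at most one non-singleton
    plane beyond the first two axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        vol = np.squeeze(vol)
        if vol.ndim != 2:
            raise ValueError(
                f"{path.name}: multi-slice NIfTI needs an explicit slice selector"
            )
        data = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        im = Image.open(path)
        arr = np.asarray(im)
        if arr.ndim == 3:
            w = np.asarray(LUMA_WEIGHTS + (0.0,))[: arr.shape[2]]
            data = np.clip(np.rint(arr.astype(np.float64) @ w), 0, 255).astype(np.uint8)
        else:
            data = arr.astype(np.uint8)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")

    if manifest_record is None:
        warnings.warn(f"{path.name}: no manifest record; metadata missing", stacklevel=2)
        return ImageSlice(pixels=data)
    return ImageSlice(
        pixels=data,
        intensity_domain="uint8",
        modality_name=manifest_record.modality_name,
        field_strength=manifest_record.field_strength,
        subject_id=manifest_record.subject_id,
        slice_index=manifest_record.slice_index,
    )
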