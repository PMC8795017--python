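"""Image preprocessing: isotropic resampling, Z-score normalization and
fixed-bin-width gray-level discretization.

The chain mirrors a standard radiomics protocol for multi-center MR data:

1. resample image and mask to isotropic 0.5 mm voxels with cubic B-spline
   interpolation (masks are interpolated as floats, then re-binarized at 0.5),
2. Z-score normalize voxel intensities (over the full volume by default),
3. discretize ROI intensities with a fixed bin width of 0.5 anchored at the
   ROI minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volume import ImageVolume, SegMask

__all__ = ["DiscretizedROI", "resample_isotropic", "znormalize", "discretize"]

DEFAULT_TARGET_MM = 0.5
DEFAULT_BIN_WIDTH = 0.5


@dataclass
class DiscretizedROI:
    """Integer gray-level grid: 0 outside the ROI, 1..n_levels inside."""

    labels: np.ndarray
    n_levels: int
    bin_width: float
    roi_min: float

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK's array view is (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def _resample(img: sitk.Image, target_mm: float, size, interpolator) -> sitk.Image:
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing((target_mm,) * 3)
    rs.SetSize([int(s) for s in size])
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())
    rs.SetInterpolator(interpolator)
    rs.SetDefaultPixelValue(0.0)
    return rs.Execute(img)


def resample_isotropic(
    img: ImageVolume, mask: SegMask, target_mm: float = DEFAULT_TARGET_MM
) -> tuple[ImageVolume, SegMask]:
    """Resample a paired image and mask to isotropic ``target_mm`` voxels.

    The image is interpolated with a cubic B-spline; the mask is interpolated
    as a float field and re-binarized at 0.5.  The output grid keeps the
    input origin and covers the input world extent (within one voxel).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")

    # keep every output voxel center inside the input sampling domain, so
    # edge voxels are interpolated rather than padding-filled; world extent
    # is preserved to within one voxel
    size = [
        max(1, int(np.floor((img.shape[a] - 1) * img.spacing[a] / target_mm + 1e-9)) + 1)
        for a in range(3)
    ]
    s_img = _to_sitk(np.asarray(img.data, dtype=np.float64), img.spacing, img.origin)
    s_msk = _to_sitk(np.asarray(mask.data, dtype=np.float64), mask.spacing, mask.origin)

    out_img = _from_sitk(_resample(s_img, target_mm, size, sitk.sitkBSpline))
    out_msk = _from_sitk(_resample(s_msk, target_mm, size, sitk.sitkBSpline)) >= 0.5

    if not out_msk.any():
        raise ValueError("ROI lost in resampling: resampled mask is empty")

    spacing = (target_mm,) * 3
    return (
        ImageVolume(out_img, spacing, img.origin),
        SegMask(out_msk.astype(np.uint8), spacing, mask.origin),
    )


def znormalize(img: ImageVolume, mask: SegMask | None = None, scope: str = "volume") -> ImageVolume:
    """Z-score normalize intensities: subtract the mean, divide by the
    population SD.  ``scope='volume'`` (default) uses full-volume statistics;
    ``scope='roi'`` restricts them to the mask.
    """
    if scope not in ("volume", "roi"):
        raise ValueError(f"scope must be 'volume' or 'roi', got {scope!r}")
    data = np.asarray(img.data, dtype=np.float64)
    ref = data if scope == "volume" or mask is None else data[mask.data > 0]
    mu = ref.mean()
    sd = ref.std()
    if sd == 0:
        raise ValueError("cannot Z-score normalize a zero-variance image")
    return ImageVolume((data - mu) / sd, img.spacing, img.origin)


def discretize(
    img: ImageVolume | np.ndarray,
    mask: SegMask | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DiscretizedROI:
    """Fixed-bin-width discretization of ROI intensities.

    Gray level of voxel x is ``floor((x - min_ROI) / bin_width) + 1``; the
    number of levels is ``floor((max - min) / bin_width) + 1``.  Bin edges
    are anchored at the ROI minimum, making the labels invariant to adding a
    constant to all intensities.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    data = np.asarray(img.data if isinstance(img, ImageVolume) else img, dtype=np.float64)
    m = np.asarray(mask.data if isinstance(mask, SegMask) else mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    vals = data[m]
    vmin = float(vals.min())
    vmax = float(vals.max())
    n_levels = int(np.floor((vmax - vmin) / bin_width)) + 1
    labels = np.zeros(data.shape, dtype=np.int64)
    labels[m] = np.clip(np.floor((data[m] - vmin) / bin_width).astype(np.int64) + 1, 1, n_levels)
    return DiscretizedROI(labels=labels, n_levels=n_levels, bin_width=bin_width, roi_min=vmin)
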