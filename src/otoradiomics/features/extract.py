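"""Full radiomic feature extraction: 812 named features per (image, mask).

The roster is 20 shape features plus 88 intensity/texture features (18
first-order "Stats", 26 GLCM, 16 GLRLM, 16 GLSZM, 7 GLDM, 5 NGTDM) computed
on the original image and on each of its eight stationary wavelet sub-bands:
20 + 9 x 88 = 812.  Names follow ``<ImageType>_<Group>_<Name>`` (shape
features, which do not depend on intensities, carry the plain ``Shape_``
prefix), e.g. ``orig_Stats_min`` or ``wavelet-HHL_GLCM_contrast``.

Each image version is independently re-discretized with the fixed 0.5 bin
width over the ROI before its histogram/texture features are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ..preprocess import DEFAULT_BIN_WIDTH, discretize
from ..volume import ImageVolume, SegMask
from .firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .wavelet import IMAGE_TYPES, wavelet_decompose

__all__ = ["ExtractionConfig", "feature_roster", "extract_all", "N_FEATURES"]

_GROUPS = (
    ("Stats", FIRSTORDER_FEATURE_NAMES),
    ("GLCM", GLCM_FEATURE_NAMES),
    ("GLRLM", GLRLM_FEATURE_NAMES),
    ("GLSZM", GLSZM_FEATURE_NAMES),
    ("GLDM", GLDM_FEATURE_NAMES),
    ("NGTDM", NGTDM_FEATURE_NAMES),
)

N_FEATURES = 812


@dataclass
class ExtractionConfig:
    """Knobs of the extraction stage."""

    bin_width: float = DEFAULT_BIN_WIDTH
    wavelet: str = "coif1"
    crop_margin: int = 8  # voxels of context kept around the ROI bounding box


def feature_roster() -> list[str]:
    """The ordered list of the 812 feature names."""
    names = [f"Shape_{n}" for n in SHAPE_FEATURE_NAMES]
    for image_type in IMAGE_TYPES:
        for group, group_names in _GROUPS:
            names.extend(f"{image_type}_{group}_{n}" for n in group_names)
    assert len(names) == N_FEATURES and len(set(names)) == N_FEATURES
    return names


def export_roster(path) -> None:
    """Write the roster manifest (name, group, image type) as JSON."""
    entries = []
    for name in feature_roster():
        if name.startswith("Shape_"):
            entries.append({"name": name, "image_type": None, "group": "Shape"})
        else:
            image_type, group, _ = name.split("_", 2)
            entries.append({"name": name, "image_type": image_type, "group": group})
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


def _crop_to_roi(img: ImageVolume, mask: SegMask, margin: int):
    """Crop image and mask to the ROI bounding box plus a fixed margin.

    The margin is taken relative to the bounding box (clipped at the volume
    edge), so whole-voxel translations of the content leave the crop —
    and hence every feature — unchanged for interior ROIs.
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, m.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return np.asarray(img.data, dtype=np.float64)[sl], m[sl]


def extract_all(
    img: ImageVolume, mask: SegMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract all 812 features from a preprocessed (image, mask) pair.

    Expects the resampled, normalized image; returns an ordered dict
    matching :func:`feature_roster`.
    """
    config = config or ExtractionConfig()
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    data, roi = _crop_to_roi(img, mask, config.crop_margin)
    voxel_volume = img.voxel_volume

    features: dict[str, float] = {}
    try:
        shp = shape_features(SegMask(mask.data, mask.spacing, mask.origin))
    except Exception as exc:
        raise RuntimeError(f"shape feature extraction failed: {exc}") from exc
    features.update({f"Shape_{k}": v for k, v in shp.items()})

    versions = {"orig": data}
    try:
        bands = wavelet_decompose(data, config.wavelet)
    except Exception as exc:
        raise RuntimeError(f"wavelet decomposition failed: {exc}") from exc
    versions.update({f"wavelet-{b}": arr for b, arr in bands.items()})

    for image_type in IMAGE_TYPES:
        arr = versions[image_type]
        disc = discretize(arr, roi, config.bin_width)
        values = arr[roi]
        for group, fn in (
            ("Stats", lambda: firstorder_features(values, disc, voxel_volume)),
            ("GLCM", lambda: glcm_features(disc)),
            ("GLRLM", lambda: glrlm_features(disc)),
            ("GLSZM", lambda: glszm_features(disc)),
            ("GLDM", lambda: gldm_features(disc)),
            ("NGTDM", lambda: ngtdm_features(disc)),
        ):
            try:
                vals = fn()
            except Exception as exc:
                raise RuntimeError(
                    f"{group} feature extraction failed on {image_type}: {exc}"
                ) from exc
            features.update({f"{image_type}_{group}_{k}": v for k, v in vals.items()})

    assert len(features) == N_FEATURES
    bad = [k for k, v in features.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite features: {bad[:5]} (+{max(0, len(bad) - 5)} more)")
    return features
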