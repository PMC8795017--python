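"""First-order (intensity histogram) statistics of ROI voxels.

18 values per image version.  Entropy and uniformity are computed on the
fixed-bin-width discretized histogram; everything else on the raw
(normalized or wavelet-filtered) intensities.  Percentiles use linear
interpolation between order statistics; variance/SD use the population
convention; kurtosis is the Pearson (non-excess) form.  Zero-variance ROIs
take skewness = kurtosis = 0.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedROI

__all__ = ["firstorder_features", "FIRSTORDER_FEATURE_NAMES"]

FIRSTORDER_FEATURE_NAMES = (
    "min",
    "max",
    "range",
    "mean",
    "median",
    "p10",
    "p90",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "total_energy",
    "rms",
    "mad",
    "robust_mad",
    "iqr",
    "entropy",
    "uniformity",
)

_EPS = np.spacing(1.0)


def firstorder_features(
    values: np.ndarray, disc: DiscretizedROI, voxel_volume: float
) -> dict[str, float]:
    """Compute the 18 first-order features.

    Parameters
    ----------
    values : 1D array of ROI intensities.
    disc : matching discretization (for entropy/uniformity).
    voxel_volume : mm^3, for total energy.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])

    if sd > 1e-12 * max(abs(mean), 1.0):  # guard against rounding-only spread
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson kurtosis (normal -> 3)
    else:
        skew = kurt = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    counts = np.bincount(disc.labels[disc.labels > 0] - 1, minlength=disc.n_levels)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p + _EPS)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "mean": mean,
        "median": float(np.median(x)),
        "p10": float(p10),
        "p90": float(p90),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "total_energy": energy * voxel_volume,
        "rms": float(np.sqrt((x**2).mean())),
        "mad": float(np.abs(x - mean).mean()),
        "robust_mad": robust_mad,
        "iqr": float(p75 - p25),
        "entropy": entropy,
        "uniformity": uniformity,
    }
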