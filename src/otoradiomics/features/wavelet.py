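"""Single-level stationary (undecimated) 3D wavelet decomposition.

The eight sub-bands LLL..HHH separate low (L) and high (H) spatial
frequencies per axis; being undecimated, every sub-band stays on the input
grid so the original segmentation mask applies unchanged.  The Coiflet-1
kernel is the default.  Axes with odd length are symmetrically padded to
even length for the transform and cropped back afterwards.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["wavelet_decompose", "SUBBAND_NAMES", "IMAGE_TYPES"]

SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
#: image versions in roster order: original plus the eight sub-bands
IMAGE_TYPES = ("orig",) + tuple(f"wavelet-{b}" for b in SUBBAND_NAMES)


def wavelet_decompose(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Decompose a 3D volume into its eight stationary wavelet sub-bands.

    Returns a dict keyed by LLL..HHH, each the same shape as ``data``.
    Letter k of the band name refers to array axis k (L = lowpass/approx,
    H = highpass/detail).
    """
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    filt_len = pywt.Wavelet(wavelet).dec_len
    if min(arr.shape) < filt_len:
        raise ValueError(
            f"volume shape {arr.shape} too small for wavelet {wavelet!r} "
            f"(filter length {filt_len})"
        )
    pad = [(0, s % 2) for s in arr.shape]
    padded = np.pad(arr, pad, mode="symmetric") if any(p[1] for p in pad) else arr

    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for band in SUBBAND_NAMES:
        key = band.replace("L", "a").replace("H", "d")
        sub = coeffs[key]
        out[band] = sub[tuple(slice(0, s) for s in arr.shape)]
    return out
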