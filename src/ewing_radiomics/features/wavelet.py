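"""Single-level stationary (undecimated) wavelet decomposition.

The undecimated transform keeps every sub-band on the input grid, so the
tumour mask applies to each sub-band without resampling. In 3D this yields
8 sub-bands (low/high-pass per axis, tags LLL..HHH, character i = array
axis i); a 2D slice yields 4 (LL, LH, HL, HH). Default basis: Coiflet-1,
configurable.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..core import InvalidParameterError

__all__ = ["wavelet_decompose", "DEFAULT_WAVELET"]

DEFAULT_WAVELET = "coif1"


def wavelet_decompose(
    data: np.ndarray, wavelet: str = DEFAULT_WAVELET
) -> list[tuple[str, np.ndarray]]:
    """Return ``[(tag, sub_band), ...]`` for a single-level stationary
    transform of a 2D or 3D array.

    Tags are 'L'/'H' per axis in array-axis order, low-pass first in the
    listing (LL.., .., HH..). Each sub-band has the input's shape. Axes are
    zero-padded to even length for the transform and cropped back.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim not in (2, 3):
        raise InvalidParameterError("wavelet_decompose expects a 2D or 3D array")
    wav = pywt.Wavelet(wavelet)
    if any(n < wav.dec_len for n in x.shape):
        raise InvalidParameterError(
            f"image shape {x.shape} smaller than filter length {wav.dec_len}"
        )
    orig_shape = x.shape
    pad = [(0, n % 2) for n in x.shape]
    if any(p[1] for p in pad):
        x = np.pad(x, pad, mode="edge")
    coeffs = pywt.swtn(x, wav, level=1)[0]
    out = []
    for key in sorted(coeffs.keys()):  # 'a' < 'd' -> low-pass first
        tag = key.replace("a", "L").replace("d", "H")
        band = coeffs[key][tuple(slice(0, n) for n in orig_shape)]
        out.append((tag, band))
    return out
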