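"""Wavelet-domain artifact removal for 360 Hz ECG.

The signal is decomposed with a 9-level Daubechies-6 ('db6') multi-resolution
filter bank.  At 360 Hz the dyadic bands are (level j): detail
``(fs/2^(j+1), fs/2^j)`` and approximation ``(0, fs/2^(j+1))``, so the
level-9 approximation spans 0-0.35 Hz (baseline wander) and details 1-2 span
45-180 Hz (50/60 Hz mains interference and high-frequency noise).  Denoising
**nullifies** whole coefficient bands — no thresholding — and reconstructs;
with nothing nullified the filter bank reconstructs the input exactly
(perfect reconstruction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

DEFAULT_WAVELET = "db6"
DEFAULT_LEVELS = 9
#: detail levels nullified by default: D1 (90-180 Hz) and D2 (45-90 Hz)
DEFAULT_ZERO_DETAILS = frozenset({1, 2})


@dataclass
class WaveletDecomposition:
    """Cascade filter-bank output: deepest approximation + details D1..DJ."""

    approx: np.ndarray
    details: list[np.ndarray]  # index 0 = D1 (finest)
    wavelet_name: str
    levels: int
    original_length: int

    def reconstruct(self) -> np.ndarray:
        """Inverse transform, trimmed to the original signal length."""
        coeffs = [self.approx] + [self.details[j] for j in range(self.levels - 1, -1, -1)]
        rec = pywt.waverec(coeffs, self.wavelet_name, mode="symmetric")
        return rec[: self.original_length]


def mra_decompose(
    signal: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> WaveletDecomposition:
    """Multi-resolution decomposition with symmetric boundary extension.

    Per-level coefficient length is ``floor((n_in + L - 1)/2)`` with L the
    filter length (12 for db6).
    """
    signal = np.asarray(signal, dtype=float)
    filt_len = pywt.Wavelet(wavelet).dec_len
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if signal.size < filt_len:
        raise ValueError(
            f"signal length {signal.size} shorter than the {wavelet} filter ({filt_len})"
        )
    # beyond ~log2(n) levels every coefficient is pure boundary extension
    if 2**levels > 2 * signal.size:
        raise ValueError(f"{levels} levels too deep for signal length {signal.size}")
    with warnings.catch_warnings():
        # deeper-than-dwt_max_level decompositions are intentional here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, wavelet, mode="symmetric", level=levels)
    approx, details_deep_first = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        approx=approx,
        details=list(reversed(details_deep_first)),
        wavelet_name=wavelet,
        levels=levels,
        original_length=signal.size,
    )


def band_of(level: int, fs: float, kind: str) -> tuple[float, float]:
    """Nominal frequency band of a decomposition output at ``level``.

    detail -> ``(fs/2^(level+1), fs/2^level)``; approx -> ``(0, fs/2^(level+1))``.
    """
    if not 1 <= level <= 9:
        raise ValueError("level must be in 1..9")
    hi = fs / 2**level
    lo = fs / 2 ** (level + 1)
    if kind == "detail":
        return (lo, hi)
    if kind == "approx":
        return (0.0, lo)
    raise ValueError(f"kind must be 'detail' or 'approx', got {kind!r}")


def denoise(
    signal: np.ndarray,
    fs: float = 360.0,
    zero_approx: bool = True,
    zero_detail_levels: frozenset[int] | set[int] = DEFAULT_ZERO_DETAILS,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Remove baseline wander and PLI by coefficient nullification.

    ``zero_approx`` zeroes the deepest approximation (0-0.35 Hz at 360 Hz /
    9 levels: baseline wander); ``zero_detail_levels`` zeroes whole detail
    bands (default {1, 2}: 45-180 Hz, covering 50/60 Hz mains interference).
    Output length equals input length.
    """
    zero_detail_levels = set(zero_detail_levels)
    if zero_detail_levels and max(zero_detail_levels) > levels:
        raise ValueError(
            f"requested detail level {max(zero_detail_levels)} exceeds {levels} levels"
        )
    dec = mra_decompose(signal, wavelet=wavelet, levels=levels)
    if zero_approx:
        dec.approx = np.zeros_like(dec.approx)
    for lev in zero_detail_levels:
        dec.details[lev - 1] = np.zeros_like(dec.details[lev - 1])
    return dec.reconstruct()
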