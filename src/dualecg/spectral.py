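"""Spectral feature vector: stacked DWT detail coefficients D3-D5.

A 5-level db6 decomposition of a 1201-sample segment (symmetric boundary
extension, per-level coefficient length ``floor((n + L - 1)/2)`` with
L = 12) yields detail lengths 606, 308, 159, 85, 48 for D1..D5.  Levels
3-5 cover 5.625-45 Hz at 360 Hz — the QRS energy band — and concatenate to
the 292-sample spectral input of the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

WAVELET = "db6"
LEVELS = 5
KEEP_LEVELS = (3, 4, 5)
SPECTRAL_LEN = 292  # len(D3)+len(D4)+len(D5) for a 1201-sample segment


def coeff_len(n: int, filter_len: int = 12) -> int:
    """Single-level DWT coefficient length: ``floor((n + filter_len - 1)/2)``."""
    if n < 1 or filter_len < 2:
        raise ValueError("need n >= 1 and filter_len >= 2")
    return (n + filter_len - 1) // 2


@dataclass
class SpectralVector:
    """Horizontally stacked detail coefficients, order D3 then D4 then D5."""

    values: np.ndarray
    section_lengths: tuple[int, int, int]
    wavelet_name: str = WAVELET

    def section(self, level: int) -> np.ndarray:
        """Slice of ``values`` holding the detail coefficients of ``level``."""
        i = KEEP_LEVELS.index(level)
        off = sum(self.section_lengths[:i])
        return self.values[off : off + self.section_lengths[i]]


def spectral_features(
    segment: np.ndarray,
    levels: int = LEVELS,
    keep: tuple[int, ...] = KEEP_LEVELS,
) -> SpectralVector:
    """Compute the stacked D3‖D4‖D5 vector of one segment.

    Any input length is accepted; section lengths follow :func:`coeff_len`.
    For the canonical 1201-sample segment the output has length 292 with
    sections (159, 85, 48).
    """
    segment = np.asarray(segment, dtype=float)
    filt_len = pywt.Wavelet(WAVELET).dec_len
    if segment.size < filt_len:
        raise ValueError(
            f"segment of {segment.size} samples is shorter than the {WAVELET} filter"
        )
    with warnings.catch_warnings():
        # short inputs trigger pywt's boundary-effect warning; lengths are
        # still governed by coeff_len, which is what callers rely on
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(segment, WAVELET, mode="symmetric", level=levels)
    # coeffs = [A_levels, D_levels, ..., D1]
    details = {levels - i: c for i, c in enumerate(coeffs[1:])}
    sections = [details[lev] for lev in keep]
    return SpectralVector(
        values=np.concatenate(sections),
        section_lengths=tuple(len(s) for s in sections),
    )


def spectral_matrix(segments: np.ndarray) -> np.ndarray:
    """Stacked spectral vectors for a (n, segment_len) matrix of segments."""
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    return np.stack([spectral_features(row).values for row in segments])
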