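"""R-peak-anchored 3-beat segmentation and feature standardization.

Each labelled beat ``i`` with two annotated neighbours on each side yields a
variable-length window around its R peak, which is then aligned to exactly
1201 samples with the central R at index 600 (1-based sample 601) by
zero-padding or cropping.  The 1201-sample target exceeds the length of
~95% of windows at typical ambulatory heart rates, so fewer than 5% of
segments are cropped.

Two extraction modes exist because the window formula admits two readings:

* ``"spanning"`` (default) — from the midpoint of (R_{i-2}, R_{i-1}) to the
  midpoint of (R_{i+1}, R_{i+2}): a genuine 3-beat window;
* ``"literal"`` — both half-widths measured from R_i itself
  (R_i - floor((R_{i-1}-R_{i-2})/2) to R_i + floor((R_{i+2}-R_{i+1})/2)),
  which spans roughly one RR interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classes import AAMI_CLASSES, EXCLUDED
from .record_io import ECGRecord

logger = logging.getLogger(__name__)

SEGMENT_LEN = 1201
R_INDEX = 600  # 0-based position of the central R peak


class BeatSkipped(Exception):
    """Raised when a beat cannot be segmented (missing neighbours)."""


@dataclass
class BeatSegment:
    """A fixed-length, R-centred, labelled heartbeat window."""

    samples: np.ndarray
    label: str
    record_id: str
    beat_ordinal: int
    r_index: int = R_INDEX

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (SEGMENT_LEN,):
            raise ValueError(f"segment must have {SEGMENT_LEN} samples")
        if self.label not in AAMI_CLASSES:
            raise ValueError(f"label {self.label!r} not an AAMI class")


@dataclass
class SegmentationStats:
    """Bookkeeping for one record's segmentation pass."""

    n_annotations: int = 0
    n_excluded: int = 0
    n_edge_skipped: int = 0
    n_emitted: int = 0
    n_cropped: int = 0
    n_padded: int = 0

    @property
    def crop_rate(self) -> float:
        return self.n_cropped / self.n_emitted if self.n_emitted else 0.0


def extract_3beat(
    signal: np.ndarray,
    r_peaks: np.ndarray,
    i: int,
    mode: str = "spanning",
) -> tuple[np.ndarray, int]:
    """Extract the variable-length window around beat ``i``.

    Returns ``(window, r_offset)`` where ``r_offset`` is the position of
    R_i inside the window.  Window boundaries are clipped to the signal.
    Raises :class:`BeatSkipped` if beat ``i`` lacks two annotated
    neighbours on either side.
    """
    signal = np.asarray(signal)
    r = np.asarray(r_peaks, dtype=int)
    if not 2 <= i <= r.size - 3:
        raise BeatSkipped(f"beat {i} lacks two neighbours on each side")
    if mode == "spanning":
        start = r[i - 1] - (r[i - 1] - r[i - 2]) // 2
        end = r[i + 1] + (r[i + 2] - r[i + 1]) // 2
    elif mode == "literal":
        start = r[i] - (r[i - 1] - r[i - 2]) // 2
        end = r[i] + (r[i + 2] - r[i + 1]) // 2
    else:
        raise ValueError(f"mode must be 'spanning' or 'literal', got {mode!r}")
    start = max(start, 0)
    end = min(end, signal.size - 1)
    return signal[start : end + 1], int(r[i] - start)


def align(segment: np.ndarray, r_offset: int, target_len: int = SEGMENT_LEN) -> np.ndarray:
    """Pad/crop to ``target_len`` with the R sample moved to the centre.

    The centre index is ``(target_len - 1) // 2`` (600 for 1201).  Padding
    value is 0 mV — after denoising the baseline sits at zero.  The output
    at the centre always equals ``segment[r_offset]``.
    """
    segment = np.asarray(segment, dtype=float)
    if not 0 <= r_offset < segment.size:
        raise ValueError("r_offset outside segment")
    center = (target_len - 1) // 2
    out = np.zeros(target_len, dtype=float)
    # source window [src_lo, src_hi) maps onto [dst_lo, dst_lo + span)
    src_lo = max(0, r_offset - center)
    src_hi = min(segment.size, r_offset + (target_len - center))
    dst_lo = center - (r_offset - src_lo)
    out[dst_lo : dst_lo + (src_hi - src_lo)] = segment[src_lo:src_hi]
    return out


def segment_record(
    record: ECGRecord,
    denoised: np.ndarray | None = None,
    mode: str = "spanning",
    with_stats: bool = False,
):
    """Segment every eligible labelled beat of a record.

    ``denoised`` is the signal to cut from (defaults to ``record.samples``).
    Beats whose class is EXCLUDED, or which lack two neighbours on each
    side, are counted in the stats and skipped.  R-peak positions come from
    the annotation stream — all annotated beats (including excluded ones)
    serve as neighbours, matching the annotation-driven window formula.
    """
    signal = record.samples if denoised is None else np.asarray(denoised, dtype=float)
    stats = SegmentationStats(n_annotations=len(record.annotations))
    r_peaks = np.array([a.sample_index for a in record.annotations], dtype=int)
    segments: list[BeatSegment] = []
    for i, ann in enumerate(record.annotations):
        if ann.aami_class == EXCLUDED:
            stats.n_excluded += 1
            continue
        try:
            window, r_off = extract_3beat(signal, r_peaks, i, mode=mode)
        except BeatSkipped:
            stats.n_edge_skipped += 1
            continue
        if window.size > SEGMENT_LEN:
            stats.n_cropped += 1
        elif window.size < SEGMENT_LEN:
            stats.n_padded += 1
        segments.append(
            BeatSegment(
                samples=align(window, r_off),
                label=ann.aami_class,
                record_id=record.record_id,
                beat_ordinal=i,
            )
        )
        stats.n_emitted += 1
    logger.info(
        "segmented %s: %d/%d beats emitted (%d excluded, %d edge-skipped), "
        "crop rate %.2f%%",
        record.record_id, stats.n_emitted, stats.n_annotations,
        stats.n_excluded, stats.n_edge_skipped, 100 * stats.crop_rate,
    )
    if with_stats:
        return segments, stats
    return segments


@dataclass
class Standardizer:
    """Scalar z-scoring fitted on training data only (one pair per channel)."""

    mean: float
    std: float

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.std


def fit_standardizer(train_matrix: np.ndarray) -> Standardizer:
    """Fit scalar mean/std over ALL entries of the training matrix.

    Population std (ddof=0).  A degenerate (constant) training matrix is an
    error rather than a divide-by-zero.
    """
    x = np.asarray(train_matrix, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit a standardizer on an empty matrix")
    std = float(x.std())
    if std == 0.0:
        raise ValueError("degenerate training matrix: zero variance")
    return Standardizer(mean=float(x.mean()), std=std)


def apply_standardizer(s: Standardizer, matrix: np.ndarray) -> np.ndarray:
    return s.apply(matrix)
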