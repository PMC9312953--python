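"""Raw-ECG preprocessing: band-pass filtering, max-min normalization,
Pan-Tompkins R-peak detection, fixed 320-sample beat segmentation and the
10-bit inter-beat interval code.

Beat geometry is fixed throughout the package: 127 samples left of the R
peak, 192 right of it, plus the peak itself (127 + 192 + 1 = 320).  The
interval code stores the signed gap between consecutive beat windows as a
flag bit (0 = delay, 1 = overlap) and a 9-bit magnitude, so any gap up to
511 samples (~1.4 s at 360 Hz) is representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .synthetic import (
    BEAT_LEFT,
    BEAT_LEN,
    BEAT_RIGHT,
    ECGRecord,
    MAX_INTERVAL_MAGNITUDE,
)

__all__ = [
    "Beat",
    "IntervalCode",
    "NormalizationParams",
    "bandpass_filter",
    "normalize_minmax",
    "denormalize",
    "detect_r_peaks",
    "segment_beats",
    "encode_interval",
    "decode_interval",
    "prepare_record",
    "PreparedRecord",
]

logger = logging.getLogger(__name__)


@dataclass
class Beat:
    """A fixed 320-sample window around one R peak."""

    samples: np.ndarray
    r_index: int
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LEN,):
            raise ValueError(f"a beat must have exactly {BEAT_LEN} samples")


@dataclass(frozen=True)
class IntervalCode:
    """Flag bit plus 9-bit magnitude: gap (flag 0) or overlap (flag 1)."""

    flag: int
    magnitude: int

    def __post_init__(self) -> None:
        if self.flag not in (0, 1):
            raise ValueError("flag must be 0 or 1")
        if not (0 <= self.magnitude <= MAX_INTERVAL_MAGNITUDE):
            raise ValueError("magnitude must fit in 9 bits (0..511)")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-record max-min normalization constants, kept for inversion."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not self.max_value > self.min_value:
            raise ValueError("max_value must exceed min_value")


def bandpass_filter(record: ECGRecord, low: float = 0.5, high: float = 150.0) -> ECGRecord:
    """0.5-150 Hz zero-phase Butterworth band-pass.

    Fourth-order sections applied forward-backward (``sosfiltfilt``) so the
    filter has no group delay and R-peak timing is preserved for the
    segmentation that follows.
    """
    nyq = record.fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    if low <= 0 or low >= high:
        raise ValueError("need 0 < low < high")
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(record.samples, dtype=float))
    return ECGRecord(
        samples=filtered,
        fs=record.fs,
        resolution_bits=record.resolution_bits,
        r_truth=record.r_truth,
        record_id=record.record_id,
    )


def normalize_minmax(record: ECGRecord) -> Tuple[ECGRecord, NormalizationParams]:
    """Map the record affinely onto [0, 1]; returns the inversion constants."""
    x = np.asarray(record.samples, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant record")
    params = NormalizationParams(min_value=lo, max_value=hi)
    out = ECGRecord(
        samples=(x - lo) / (hi - lo),
        fs=record.fs,
        resolution_bits=record.resolution_bits,
        r_truth=record.r_truth,
        record_id=record.record_id,
    )
    return out, params


def denormalize(samples: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Inverse of :func:`normalize_minmax` on a plain sample array."""
    x = np.asarray(samples, dtype=float)
    return x * (params.max_value - params.min_value) + params.min_value


def detect_r_peaks(record: ECGRecord) -> np.ndarray:
    """Pan-Tompkins QRS detection, zero-phase variant.

    Stages: 5-15 Hz band-pass (sosfiltfilt), symmetric derivative, squaring,
    centered 150 ms moving-window integration, adaptive signal/noise peak
    thresholds with a 200 ms refractory period, then refinement of each
    fiducial to the dominant deflection of the input samples.  Because every
    stage is zero-phase the integrator peak is time-aligned with the QRS,
    which is what makes sample-exact refinement possible.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = record.fs
    if x.shape[0] < 2 * fs:
        raise ValueError("record shorter than 2 s; R-peak detection needs context")
    if np.ptp(x) == 0:
        return np.asarray([], dtype=np.int64)

    nyq = fs / 2.0
    sos = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = sps.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.asarray([], dtype=np.int64)

    # Adaptive thresholding per the classic running estimates.
    spki = 0.5 * float(mwi[cand].max())
    npki = 0.25 * float(np.mean(mwi))
    accepted: List[int] = []
    for c in cand:
        peak = float(mwi[c])
        threshold = npki + 0.25 * (spki - npki)
        if peak >= threshold:
            accepted.append(int(c))
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
    if not accepted:
        return np.asarray([], dtype=np.int64)

    # Refine each fiducial to the strongest deflection of the input within
    # half an integration window; baseline taken as the local median so both
    # positive and negative R waves refine correctly.
    half = win // 2 + 5
    refined: List[int] = []
    for c in accepted:
        lo = max(0, c - half)
        hi = min(x.shape[0], c + half + 1)
        seg = x[lo:hi]
        r = lo + int(np.argmax(np.abs(seg - np.median(seg))))
        if refined and r - refined[-1] < refractory:
            # keep the larger of the two colliding refinements
            if np.abs(x[r] - np.median(seg)) <= np.abs(x[refined[-1]] - np.median(seg)):
                continue
            refined[-1] = r
        else:
            refined.append(r)
    return np.asarray(sorted(set(refined)), dtype=np.int64)


def segment_beats(record: ECGRecord, r_indices: Sequence[int]) -> List[Beat]:
    """Cut a 320-sample window (127 left, 192 right, ends inclusive) per R.

    R peaks too close to either record boundary are skipped; the count of
    skipped beats is logged, not raised.
    """
    x = np.asarray(record.samples, dtype=float)
    n = x.shape[0]
    beats: List[Beat] = []
    skipped = 0
    for r in r_indices:
        r = int(r)
        if r < BEAT_LEFT or r + BEAT_RIGHT >= n:
            skipped += 1
            continue
        beats.append(
            Beat(
                samples=x[r - BEAT_LEFT : r + BEAT_RIGHT + 1],
                r_index=r,
                record_id=record.record_id,
            )
        )
    if skipped:
        logger.info(
            "segment_beats: skipped %d boundary beat(s) of %d in record %r",
            skipped,
            len(list(r_indices)),
            record.record_id,
        )
    return beats


def encode_interval(rr: int, beat_len: int = BEAT_LEN) -> IntervalCode:
    """Encode the gap between consecutive beat windows.

    ``gap = rr - beat_len``; non-negative gaps are delays (flag 0), negative
    gaps are overlaps (flag 1) with the magnitude stored absolute.
    """
    gap = int(rr) - beat_len
    if abs(gap) > MAX_INTERVAL_MAGNITUDE:
        raise ValueError(
            f"gap {gap} exceeds 9-bit interval range (+/-{MAX_INTERVAL_MAGNITUDE})"
        )
    if gap >= 0:
        return IntervalCode(flag=0, magnitude=gap)
    return IntervalCode(flag=1, magnitude=-gap)


def decode_interval(code: IntervalCode) -> int:
    """Signed gap in samples: +magnitude for flag 0, -magnitude for flag 1."""
    return code.magnitude if code.flag == 0 else -code.magnitude


@dataclass
class PreparedRecord:
    """A record taken through the full preprocessing stage.

    ``beats`` is an (n_beats, 320) float array on the normalized [0, 1]
    scale; ``intervals`` has one code per beat, the first being the
    no-predecessor convention (flag 0, magnitude 0).
    """

    beats: np.ndarray
    intervals: List[IntervalCode]
    r_indices: np.ndarray
    norm: NormalizationParams
    normalized: ECGRecord
    record_id: str = ""


def prepare_record(record: ECGRecord, use_truth_peaks: bool = False) -> PreparedRecord:
    """Filter, normalize, detect (or trust ``r_truth``), segment and encode.

    The pipeline entry used by training, compression and evaluation alike.
    """
    filtered = bandpass_filter(record)
    normalized, norm = normalize_minmax(filtered)
    if use_truth_peaks:
        if record.r_truth is None:
            raise ValueError("record carries no ground-truth R indices")
        r = np.asarray(record.r_truth, dtype=np.int64)
    else:
        r = detect_r_peaks(normalized)
    beats = segment_beats(normalized, r)
    kept_r = np.asarray([b.r_index for b in beats], dtype=np.int64)
    intervals: List[IntervalCode] = []
    for k, beat in enumerate(beats):
        if k == 0:
            intervals.append(IntervalCode(flag=0, magnitude=0))
        else:
            rr = int(kept_r[k] - kept_r[k - 1])
            intervals.append(encode_interval(rr))
    arr = (
        np.stack([b.samples for b in beats], axis=0)
        if beats
        else np.zeros((0, BEAT_LEN), dtype=float)
    )
    return PreparedRecord(
        beats=arr,
        intervals=intervals,
        r_indices=kept_r,
        norm=norm,
        normalized=normalized,
        record_id=record.record_id,
    )
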