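"""Bit-exact compression packaging and record reconstruction.

One heartbeat becomes a 30-bit pack: the 10-bit interval code (flag bit,
then the 9-bit magnitude most-significant-bit first) followed by the 20
bottleneck bits in encoder output order.  Packs are concatenated
bit-contiguously into a ``.becg`` stream behind a small byte-aligned header
(magic ``BECG``, version, sampling rate, ADC resolution, beat count and the
per-record normalization constants needed to restore absolute amplitude —
the 30-bit pack itself carries no amplitude information).

Reconstruction decodes each pack, optionally refines each beat with the
RECN, then stitches beats back into a continuous record: positive gaps are
filled by linear interpolation between the neighboring samples, overlaps are
replaced by the mean of the two overlapping segments.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bcae import BCAE, CODE_BITS
from .preprocessing import (
    IntervalCode,
    NormalizationParams,
    decode_interval,
    denormalize,
    prepare_record,
)
from .recn import RECN, compensate
from .synthetic import BEAT_LEN, ECGRecord

__all__ = [
    "PACK_BITS",
    "INTERVAL_BITS",
    "CompressedStream",
    "pack",
    "unpack",
    "compress_record",
    "stitch_record",
    "decompress_stream",
    "roundtrip_record",
]

INTERVAL_BITS = 10
PACK_BITS = INTERVAL_BITS + CODE_BITS

_MAGIC = b"BECG"
_VERSION = 1
_HEADER = struct.Struct("<4sBdBIdd")  # magic, version, fs, bits, count, min, max


def pack(interval: IntervalCode, code: np.ndarray) -> np.ndarray:
    """One 30-bit unit as a uint8 bit array: [flag][magnitude MSB first][code]."""
    code = np.asarray(code)
    if code.shape != (CODE_BITS,):
        raise ValueError(f"code must have {CODE_BITS} bits")
    if not np.isin(code, (0, 1)).all():
        raise ValueError("code bits must be 0/1")
    bits = np.empty(PACK_BITS, dtype=np.uint8)
    bits[0] = interval.flag
    for i in range(9):
        bits[1 + i] = (interval.magnitude >> (8 - i)) & 1
    bits[INTERVAL_BITS:] = code.astype(np.uint8)
    return bits


def unpack(bits: np.ndarray) -> Tuple[IntervalCode, np.ndarray]:
    """Inverse of :func:`pack`."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (PACK_BITS,):
        raise ValueError(f"a pack has exactly {PACK_BITS} bits")
    flag = int(bits[0])
    magnitude = 0
    for i in range(9):
        magnitude = (magnitude << 1) | int(bits[1 + i])
    return IntervalCode(flag=flag, magnitude=magnitude), bits[INTERVAL_BITS:].copy()


@dataclass
class CompressedStream:
    """A compressed record: header fields plus the concatenated 30-bit packs."""

    fs: float
    resolution_bits: int
    norm: NormalizationParams
    intervals: List[IntervalCode] = field(default_factory=list)
    codes: List[np.ndarray] = field(default_factory=list)

    @property
    def beat_count(self) -> int:
        return len(self.codes)

    @property
    def payload_bits(self) -> int:
        return PACK_BITS * self.beat_count

    def serialize(self) -> bytes:
        header = _HEADER.pack(
            _MAGIC,
            _VERSION,
            float(self.fs),
            int(self.resolution_bits),
            self.beat_count,
            self.norm.min_value,
            self.norm.max_value,
        )
        if self.beat_count:
            bits = np.concatenate(
                [pack(iv, c) for iv, c in zip(self.intervals, self.codes)]
            )
        else:
            bits = np.zeros(0, dtype=np.uint8)
        return header + np.packbits(bits).tobytes()

    @classmethod
    def deserialize(cls, data: bytes) -> "CompressedStream":
        if len(data) < _HEADER.size:
            raise ValueError("truncated stream header")
        magic, version, fs, bits_res, count, lo, hi = _HEADER.unpack_from(data)
        if magic != _MAGIC:
            raise ValueError("not a BECG stream (bad magic)")
        if version != _VERSION:
            raise ValueError(f"unsupported stream version {version}")
        need_bits = PACK_BITS * count
        payload = np.frombuffer(data, dtype=np.uint8, offset=_HEADER.size)
        bits = np.unpackbits(payload)
        if bits.size < need_bits:
            got = bits.size // PACK_BITS
            raise ValueError(f"truncated payload at pack {got} of {count}")
        stream = cls(
            fs=fs,
            resolution_bits=bits_res,
            norm=NormalizationParams(min_value=lo, max_value=hi),
        )
        for k in range(count):
            iv, code = unpack(bits[k * PACK_BITS : (k + 1) * PACK_BITS])
            stream.intervals.append(iv)
            stream.codes.append(code)
        return stream

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.serialize())

    @classmethod
    def read(cls, path) -> "CompressedStream":
        with open(path, "rb") as fh:
            return cls.deserialize(fh.read())


def compress_record(
    record: ECGRecord, bcae_model: BCAE, use_truth_peaks: bool = False
) -> CompressedStream:
    """Preprocess, encode every beat, and emit one pack per beat in order."""
    prep = prepare_record(record, use_truth_peaks=use_truth_peaks)
    stream = CompressedStream(
        fs=record.fs, resolution_bits=record.resolution_bits, norm=prep.norm
    )
    if prep.beats.shape[0]:
        codes = bcae_model.encode_batch(prep.beats)
        stream.codes = [c.astype(np.uint8) for c in codes]
        stream.intervals = list(prep.intervals)
    return stream


def stitch_record(
    beats: Sequence[np.ndarray], intervals: Sequence[IntervalCode]
) -> np.ndarray:
    """Assemble reconstructed beats into a continuous signal.

    The first beat is placed at the origin.  For each subsequent beat the
    decoded gap g relative to the previous 320-sample window is applied:
    g > 0 inserts g linearly interpolated samples, g < 0 averages the
    |g|-sample overlap of the two windows, g = 0 abuts them.
    """
    beats = [np.asarray(b, dtype=float) for b in beats]
    if len(beats) != len(intervals):
        raise ValueError("need exactly one interval code per beat")
    if not beats:
        return np.zeros(0, dtype=float)
    for b in beats:
        if b.shape != (BEAT_LEN,):
            raise ValueError(f"each beat must have {BEAT_LEN} samples")
    out = list(beats[0])
    for beat, code in zip(beats[1:], intervals[1:]):
        gap = decode_interval(code)
        if gap > 0:
            a, bfirst = out[-1], beat[0]
            step = (bfirst - a) / (gap + 1)
            out.extend(a + step * (i + 1) for i in range(gap))
            out.extend(beat)
        elif gap == 0:
            out.extend(beat)
        else:
            v = -gap
            if v >= BEAT_LEN:
                raise ValueError(f"overlap {v} >= beat length {BEAT_LEN}")
            tail = np.asarray(out[-v:])
            out[-v:] = list((tail + beat[:v]) / 2.0)
            out.extend(beat[v:])
    return np.asarray(out, dtype=float)


def decompress_stream(
    stream: CompressedStream,
    bcae_model: BCAE,
    recn_model: Optional[RECN] = None,
    denormalize_output: bool = True,
) -> ECGRecord:
    """Decode every pack, refine with RECN if given, stitch and denormalize."""
    if stream.beat_count == 0:
        return ECGRecord(
            samples=np.zeros(0, dtype=float),
            fs=stream.fs,
            resolution_bits=stream.resolution_bits,
        )
    codes = np.stack(stream.codes).astype(float)
    beats = bcae_model.decode_batch(codes)
    if recn_model is not None:
        beats = compensate(beats, recn_model.forward(codes))
    signal = stitch_record(list(beats), stream.intervals)
    if denormalize_output:
        signal = denormalize(signal, stream.norm)
    return ECGRecord(
        samples=signal, fs=stream.fs, resolution_bits=stream.resolution_bits
    )


def roundtrip_record(
    record: ECGRecord,
    bcae_model: BCAE,
    recn_model: Optional[RECN] = None,
    use_truth_peaks: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Compress and reconstruct; return aligned (original, reconstruction).

    Both signals are on the normalized [0, 1] scale (where the quality
    metrics are computed); the original is the preprocessed record cropped to
    the span covered by the encoded beats, which the stitched-length law
    makes exactly as long as the reconstruction.
    """
    prep = prepare_record(record, use_truth_peaks=use_truth_peaks)
    if prep.beats.shape[0] == 0:
        raise ValueError("no beats to round-trip")
    codes = bcae_model.encode_batch(prep.beats)
    beats = bcae_model.decode_batch(codes)
    if recn_model is not None:
        beats = compensate(beats, recn_model.forward(codes))
    recon = stitch_record(list(beats), prep.intervals)
    r_first, r_last = int(prep.r_indices[0]), int(prep.r_indices[-1])
    original = np.asarray(prep.normalized.samples, dtype=float)[
        r_first - 127 : r_last + 192 + 1
    ]
    if original.shape != recon.shape:
        raise AssertionError(
            f"alignment failure: original {original.shape} vs recon {recon.shape}"
        )
    return original, recon
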