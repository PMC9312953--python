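"""Reconstruction-quality and compression-efficiency metrics.

Six criteria: compression ratio CR = c_i/c_o; SNR (dB) of signal variance
around its mean versus error energy; RMS error; percentage RMS difference
PRD (relative to raw signal energy) and its mean-normalized variant PRDN;
and the quality score QS = CR/PRD.  Per-signal the identity
``SNR = 40 - 20 log10(PRDN)`` holds exactly.

``evaluate`` aggregates per-record metrics by arithmetic mean of the
per-record values — including QS, which is why an aggregate QS generally
differs from CR divided by the aggregate PRD.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "compression_ratio",
    "prd",
    "prdn",
    "snr",
    "rms",
    "qs",
    "evaluate",
]


def compression_ratio(ci: float, co: float) -> float:
    """Input bits over compressed bits."""
    if co <= 0:
        raise ValueError("compressed size must be positive")
    return ci / co


def _pair(do, dr) -> Tuple[np.ndarray, np.ndarray]:
    do = np.asarray(do, dtype=float)
    dr = np.asarray(dr, dtype=float)
    if do.shape != dr.shape:
        raise ValueError("signals must have equal shapes")
    if do.size == 0:
        raise ValueError("signals must be non-empty")
    return do, dr


def prd(do, dr) -> float:
    """Percentage RMS difference relative to raw signal energy."""
    do, dr = _pair(do, dr)
    denom = np.sum(do * do)
    if denom == 0:
        raise ValueError("PRD undefined for an all-zero original")
    return 100.0 * float(np.sqrt(np.sum((do - dr) ** 2) / denom))


def prdn(do, dr) -> float:
    """Mean-normalized PRD; invariant to a common offset of both signals."""
    do, dr = _pair(do, dr)
    dm = do.mean()
    denom = np.sum((do - dm) ** 2)
    if denom == 0:
        raise ValueError("PRDN undefined for a constant original")
    return 100.0 * float(np.sqrt(np.sum((do - dr) ** 2) / denom))


def snr(do, dr) -> float:
    """10 log10 of signal variance-energy over error energy, in dB.

    A perfect reconstruction has zero error energy; the documented sentinel
    for that case is +inf.
    """
    do, dr = _pair(do, dr)
    dm = do.mean()
    sig = np.sum((do - dm) ** 2)
    if sig == 0:
        raise ValueError("SNR undefined for a constant original")
    err = np.sum((do - dr) ** 2)
    if err == 0:
        return float("inf")
    return 10.0 * float(np.log10(sig / err))


def rms(do, dr) -> float:
    """Root-mean-square reconstruction error."""
    do, dr = _pair(do, dr)
    return float(np.sqrt(np.sum((do - dr) ** 2) / do.size))


def qs(cr: float, prd_value: float) -> float:
    """Quality score: compression ratio per percent of distortion."""
    if prd_value <= 0:
        raise ValueError("QS undefined for PRD <= 0")
    return cr / prd_value


def evaluate(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    record_ids: Optional[Sequence[str]] = None,
    bits_in: float = 320 * 11,
    bits_out: float = 30,
) -> pd.DataFrame:
    """Per-record metrics table plus an aggregate row of per-record means.

    ``pairs`` holds (original, reconstructed) signals on a common scale;
    ``bits_in``/``bits_out`` set the per-beat bit accounting for CR.  QS is
    NaN-guarded where a record reconstructs perfectly (PRD = 0).
    """
    if not len(pairs):
        raise ValueError("no record pairs to evaluate")
    ids = list(record_ids) if record_ids is not None else [str(i) for i in range(len(pairs))]
    cr = compression_ratio(bits_in, bits_out)
    rows = []
    for rid, (do, dr) in zip(ids, pairs):
        p = prd(do, dr)
        rows.append(
            {
                "record": rid,
                "cr": cr,
                "prd": p,
                "prdn": prdn(do, dr),
                "rms": rms(do, dr),
                "snr": snr(do, dr),
                "qs": qs(cr, p) if p > 0 else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    agg = table.drop(columns="record").mean(numeric_only=True)
    agg["record"] = "average"
    table = pd.concat([table, agg.to_frame().T], ignore_index=True)
    return table[["record", "cr", "prd", "prdn", "rms", "snr", "qs"]]
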