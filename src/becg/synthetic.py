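"""Seedable synthetic single-lead ECG generation.

Produces 360 Hz, 11-bit-quantized records with P-QRS-T morphology built from
five Gaussian bumps per beat, variable RR intervals drawn from a truncated
normal, sinusoidal baseline wander and additive Gaussian noise.  The point is
statistical structure at the beat scale — fixed-width beat windows anchored on
a dominant R deflection, rhythms in the few-hundred-sample range — not
clinical fidelity.

Ground-truth R positions are carried on the record (``r_truth``) so that
R-peak detection and segmentation can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "MorphologyParams",
    "RhythmParams",
    "ECGRecord",
    "generate_beat_template",
    "generate_record",
    "MORPHOLOGY_PRESETS",
    "RHYTHM_PRESETS",
    "PRESETS",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Beat window geometry shared with the preprocessing stage: 127 samples left
#: of the R peak, 192 right, R itself → 320 samples.
BEAT_LEFT = 127
BEAT_RIGHT = 192
BEAT_LEN = BEAT_LEFT + BEAT_RIGHT + 1

#: Inter-beat gaps must fit a 9-bit magnitude (see the interval code).
MAX_INTERVAL_MAGNITUDE = 511


@dataclass(frozen=True)
class MorphologyParams:
    """Five-Gaussian P-QRS-T beat shape.

    ``wave_centers`` are sample offsets relative to the R peak,
    ``wave_amplitudes`` are dimensionless (R must dominate in magnitude),
    ``wave_widths`` are Gaussian standard deviations in samples.
    """

    wave_centers: tuple = (-55.0, -12.0, 0.0, 12.0, 62.0)
    wave_amplitudes: tuple = (0.12, -0.10, 1.00, -0.22, 0.30)
    wave_widths: tuple = (9.0, 3.0, 4.5, 3.5, 16.0)

    def __post_init__(self) -> None:
        for name in ("wave_centers", "wave_amplitudes", "wave_widths"):
            if len(getattr(self, name)) != 5:
                raise ValueError(f"{name} must have 5 entries (P,Q,R,S,T)")
        if any(w <= 0 for w in self.wave_widths):
            raise ValueError("wave widths must be positive")
        amps = np.abs(np.asarray(self.wave_amplitudes, dtype=float))
        r = WAVE_NAMES.index("R")
        others = np.delete(amps, r)
        # degenerate all-zero morphology is allowed (useful as a null case)
        if amps.any() and not np.all(amps[r] > others):
            raise ValueError("R amplitude must be strictly largest in magnitude")


@dataclass(frozen=True)
class RhythmParams:
    """Rhythm and corruption parameters, all in record units.

    ``rr_mean``/``rr_sd`` are in samples (360 Hz → 327 samples ≈ 66 bpm);
    ``noise_sd`` and ``baseline_amp`` are relative to the unit R amplitude.
    """

    rr_mean: float = 327.02
    rr_sd: float = 18.0
    n_beats: int = 30
    noise_sd: float = 0.02
    baseline_amp: float = 0.08
    baseline_freq: float = 0.33

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.rr_mean - 3.0 * self.rr_sd <= 0:
            raise ValueError("rr_mean - 3*rr_sd must be positive")
        lo = max(1, BEAT_LEN - MAX_INTERVAL_MAGNITUDE)
        hi = BEAT_LEN + MAX_INTERVAL_MAGNITUDE
        if not (lo <= self.rr_mean <= hi):
            raise ValueError(
                f"rr_mean {self.rr_mean} outside encodable range [{lo}, {hi}]"
            )


@dataclass
class ECGRecord:
    """A continuous sampled single-lead ECG.

    ``samples`` are ADC integer counts after generation/quantization, or
    floats once filtered/normalized downstream.  ``r_truth`` holds
    ground-truth R indices when the record is synthetic.
    """

    samples: np.ndarray
    fs: float = 360.0
    resolution_bits: int = 11
    r_truth: Optional[np.ndarray] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.r_truth is not None:
            self.r_truth = np.asarray(self.r_truth, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.samples.shape[0])


def generate_beat_template(
    morph: MorphologyParams, length: int = BEAT_LEN, r_position: int = BEAT_LEFT
) -> np.ndarray:
    """Sum of five Gaussian bumps, one per wave, R anchored at ``r_position``.

    Raises if any wave (center ± 3 widths) extends beyond the template.
    """
    t = np.arange(length, dtype=float)
    out = np.zeros(length, dtype=float)
    for name, c, a, w in zip(
        WAVE_NAMES, morph.wave_centers, morph.wave_amplitudes, morph.wave_widths
    ):
        if a == 0.0:
            continue
        center = r_position + c
        if center - 3.0 * w < 0 or center + 3.0 * w > length - 1:
            raise ValueError(
                f"wave {name} (center {center:+.1f}, width {w}) extends "
                f"beyond template of length {length}"
            )
        out += a * np.exp(-0.5 * ((t - center) / w) ** 2)
    return out


def _draw_rr(rng: np.random.Generator, rhythm: RhythmParams, max_retries: int = 100) -> int:
    """One RR draw from a truncated normal over the interval-encodable range."""
    lo = max(1, BEAT_LEN - MAX_INTERVAL_MAGNITUDE)
    hi = BEAT_LEN + MAX_INTERVAL_MAGNITUDE
    for _ in range(max_retries):
        rr = int(round(rng.normal(rhythm.rr_mean, rhythm.rr_sd)))
        if lo <= rr <= hi:
            return rr
    raise RuntimeError(
        f"could not draw an encodable RR interval in {max_retries} tries "
        f"(rr_mean={rhythm.rr_mean}, rr_sd={rhythm.rr_sd})"
    )


def generate_record(
    morph: MorphologyParams,
    rhythm: RhythmParams,
    seed: int,
    record_id: str = "synthetic",
) -> ECGRecord:
    """Generate a quantized record; identical seed gives identical samples.

    Beats are templates placed at R positions accumulated from truncated-normal
    RR draws; baseline wander (sinusoid with random phase) and white Gaussian
    noise are added before affine quantization of the whole record to
    ``[0, 2^11 - 1]`` with round-half-to-even.
    """
    rng = np.random.default_rng(seed)
    r_positions = [BEAT_LEFT]
    for _ in range(rhythm.n_beats - 1):
        r_positions.append(r_positions[-1] + _draw_rr(rng, rhythm))
    r_positions = np.asarray(r_positions, dtype=np.int64)

    n = int(r_positions[-1]) + BEAT_RIGHT + 1
    signal = np.zeros(n, dtype=float)
    template = generate_beat_template(morph)
    for r in r_positions:
        signal[r - BEAT_LEFT : r + BEAT_RIGHT + 1] += template

    if rhythm.baseline_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / 360.0
        signal += rhythm.baseline_amp * np.sin(
            2.0 * np.pi * rhythm.baseline_freq * t + phase
        )
    if rhythm.noise_sd > 0:
        signal += rng.normal(0.0, rhythm.noise_sd, size=n)

    resolution_bits = 11
    full_scale = float(2**resolution_bits - 1)
    lo, hi = float(signal.min()), float(signal.max())
    if hi == lo:  # degenerate (all-zero morphology, no noise): map to mid-scale
        quant = np.full(n, round(full_scale / 2), dtype=np.int64)
    else:
        quant = np.rint((signal - lo) / (hi - lo) * full_scale).astype(np.int64)
    return ECGRecord(
        samples=quant,
        fs=360.0,
        resolution_bits=resolution_bits,
        r_truth=r_positions,
        record_id=record_id,
    )


# ---------------------------------------------------------------------------
# Presets: three distinct morphologies paired with the three rhythm regimes
# observed on the classic variable-rhythm benchmark records (mean RR 286.05,
# 422.85 and 327.02 samples at 360 Hz).

MORPHOLOGY_PRESETS = {
    # unremarkable morphology
    "typical": MorphologyParams(),
    # tall, broad T wave and deeper S
    "tall_t": MorphologyParams(
        wave_centers=(-58.0, -11.0, 0.0, 13.0, 70.0),
        wave_amplitudes=(0.10, -0.08, 1.00, -0.30, 0.55),
        wave_widths=(9.0, 3.0, 5.0, 4.0, 22.0),
    ),
    # wide QRS, low flattened T
    "wide_qrs": MorphologyParams(
        wave_centers=(-60.0, -16.0, 0.0, 16.0, 66.0),
        wave_amplitudes=(0.09, -0.18, 1.00, -0.35, 0.12),
        wave_widths=(10.0, 6.0, 8.0, 7.0, 18.0),
    ),
}

RHYTHM_PRESETS = {
    "fast": RhythmParams(rr_mean=286.05, rr_sd=14.0),
    "slow": RhythmParams(rr_mean=422.85, rr_sd=22.0),
    "intermediate": RhythmParams(rr_mean=327.02, rr_sd=18.0),
}

#: Named full presets used by the CLI and the demonstration corpus.
PRESETS = {
    "fast_typical": (MORPHOLOGY_PRESETS["typical"], RHYTHM_PRESETS["fast"]),
    "slow_tall_t": (MORPHOLOGY_PRESETS["tall_t"], RHYTHM_PRESETS["slow"]),
    "intermediate_wide_qrs": (
        MORPHOLOGY_PRESETS["wide_qrs"],
        RHYTHM_PRESETS["intermediate"],
    ),
}


def generate_preset_record(
    preset: str, n_beats: int, seed: int, record_id: Optional[str] = None
) -> ECGRecord:
    """Convenience wrapper: generate a record from a named preset."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    morph, rhythm = PRESETS[preset]
    rhythm = replace(rhythm, n_beats=n_beats)
    return generate_record(morph, rhythm, seed, record_id=record_id or preset)
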