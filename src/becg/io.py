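"""File formats: a minimal WFDB subset, CSV signals and HDF5 checkpoints.

The WFDB support covers what the pipeline needs — single- or multi-channel
format-16 signal files with a plain-text header, and MIT-format annotation
files holding R-peak positions (annotation code 1, ``N``, with SKIP words
for long intervals).  It is a deliberately small subset written for
self-consistent round trips, not a general reader for every WFDB variant.

Checkpoints store every parameter array of the auto-encoder and the RECN in
one HDF5 container together with the JSON-serialized layer specification,
so a checkpoint is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import List, Optional, Tuple

import h5py
import numpy as np

from .bcae import BCAE, LayerSpec, build_bcae
from .recn import RECN, RECNSpec, build_recn
from .synthetic import ECGRecord

__all__ = [
    "write_wfdb",
    "read_wfdb",
    "write_csv",
    "read_csv",
    "save_checkpoint",
    "load_checkpoint",
]

_ANN_NORMAL = 1  # annotation code for a normal beat
_ANN_SKIP = 59


# ---------------------------------------------------------------------------
# WFDB subset


def write_wfdb(record: ECGRecord, path_prefix: str, description: str = "MLII") -> None:
    """Write ``<prefix>.hea`` + ``<prefix>.dat`` (format 16) and, when the
    record carries ground-truth R positions, ``<prefix>.atr``."""
    name = os.path.basename(path_prefix)
    x = np.asarray(record.samples)
    samples = np.rint(x).astype(np.int16)
    n = samples.shape[0]
    init = int(samples[0]) if n else 0
    cksum = int(np.int16(samples.astype(np.int64).sum() & 0xFFFF))
    with open(path_prefix + ".hea", "w") as fh:
        fh.write(f"{name} 1 {record.fs:g} {n}\n")
        fh.write(
            f"{name}.dat 16 200(0)/adu {record.resolution_bits} 0 "
            f"{init} {cksum} 0 {description}\n"
        )
    samples.astype("<i2").tofile(path_prefix + ".dat")
    if record.r_truth is not None and len(record.r_truth):
        _write_annotations(path_prefix + ".atr", np.asarray(record.r_truth))


def _write_annotations(path: str, positions: np.ndarray) -> None:
    words: List[int] = []
    prev = 0
    for pos in positions:
        interval = int(pos) - prev
        prev = int(pos)
        if interval > 1023:
            words.append(_ANN_SKIP << 10)
            words.append((interval >> 16) & 0xFFFF)  # high word first
            words.append(interval & 0xFFFF)
            interval = 0
        words.append((_ANN_NORMAL << 10) | (interval & 0x3FF))
    words.append(0)  # end of annotations
    np.asarray(words, dtype="<u2").tofile(path)


def _read_annotations(path: str) -> np.ndarray:
    words = np.fromfile(path, dtype="<u2")
    positions: List[int] = []
    t = 0
    i = 0
    while i < words.size:
        word = int(words[i])
        if word == 0:
            break
        code = word >> 10
        interval = word & 0x3FF
        if code == _ANN_SKIP:
            long_interval = (int(words[i + 1]) << 16) | int(words[i + 2])
            t += long_interval
            i += 3
            continue
        t += interval
        if code == _ANN_NORMAL:
            positions.append(t)
        i += 1
    return np.asarray(positions, dtype=np.int64)


def read_wfdb(path_prefix: str, channel: int = 0) -> ECGRecord:
    """Read one channel of a format-16 WFDB record written by this package
    (or any conforming minimal header)."""
    hea = path_prefix + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing header file {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nsig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if not (0 <= channel < nsig):
        raise ValueError(f"channel {channel} out of range for {nsig} signal(s)")
    sig_line = lines[1 + channel].split()
    dat_file = os.path.join(os.path.dirname(path_prefix) or ".", sig_line[0])
    fmt = sig_line[1]
    if fmt.split("x")[0] != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    resolution = int(sig_line[3]) if len(sig_line) > 3 else 12
    raw = np.fromfile(dat_file, dtype="<i2")
    data = raw.reshape(-1, nsig)[:, channel].astype(np.int64)
    atr = path_prefix + ".atr"
    r_truth = _read_annotations(atr) if os.path.exists(atr) else None
    return ECGRecord(
        samples=data,
        fs=fs,
        resolution_bits=resolution,
        r_truth=r_truth,
        record_id=os.path.basename(path_prefix),
    )


# ---------------------------------------------------------------------------
# CSV


def write_csv(record: ECGRecord, path: str) -> None:
    """One sample per line."""
    np.savetxt(path, np.asarray(record.samples), fmt="%.10g")


def read_csv(path: str, fs: float = 360.0, resolution_bits: int = 11) -> ECGRecord:
    samples = np.loadtxt(path)
    return ECGRecord(
        samples=np.atleast_1d(samples),
        fs=fs,
        resolution_bits=resolution_bits,
        record_id=os.path.splitext(os.path.basename(path))[0],
    )


# ---------------------------------------------------------------------------
# checkpoints


def _layer_datasets(model) -> List[Tuple[str, str, np.ndarray]]:
    out = []
    layers = model.layers() if isinstance(model, BCAE) else model.layers
    for i, layer in enumerate(layers):
        for name, arr in layer.params().items():
            out.append((f"{i:02d}_{layer.name}", name, arr))
    return out


def save_checkpoint(
    path: str,
    bcae_model: Optional[BCAE] = None,
    recn_model: Optional[RECN] = None,
    meta: Optional[dict] = None,
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "becg-checkpoint"
        fh.attrs["meta"] = json.dumps(meta or {})
        if bcae_model is not None:
            grp = fh.create_group("bcae")
            grp.attrs["spec"] = json.dumps(
                {
                    "encoder": [dataclasses.asdict(s) for s in bcae_model.encoder_spec],
                    "decoder": [dataclasses.asdict(s) for s in bcae_model.decoder_spec],
                }
            )
            for lname, pname, arr in _layer_datasets(bcae_model):
                grp.create_dataset(f"{lname}/{pname}", data=arr)
        if recn_model is not None:
            grp = fh.create_group("recn")
            grp.attrs["spec"] = json.dumps(dataclasses.asdict(recn_model.spec))
            for lname, pname, arr in _layer_datasets(recn_model):
                grp.create_dataset(f"{lname}/{pname}", data=arr)


def load_checkpoint(path: str) -> Tuple[Optional[BCAE], Optional[RECN], dict]:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs.get("meta", "{}"))
        bcae_model = None
        recn_model = None
        if "bcae" in fh:
            spec = json.loads(fh["bcae"].attrs["spec"])
            enc = [LayerSpec(**d) for d in spec["encoder"]]
            dec = [LayerSpec(**d) for d in spec["decoder"]]
            bcae_model = build_bcae((enc, dec))
            for lname, pname, arr in _layer_datasets(bcae_model):
                arr[...] = fh["bcae"][lname][pname][()]
        if "recn" in fh:
            spec = json.loads(fh["recn"].attrs["spec"])
            spec["hidden_widths"] = tuple(spec["hidden_widths"])
            recn_model = build_recn(RECNSpec(**spec))
            for lname, pname, arr in _layer_datasets(recn_model):
                arr[...] = fh["recn"][lname][pname][()]
    return bcae_model, recn_model, meta
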