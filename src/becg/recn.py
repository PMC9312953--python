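"""Residual error compensation network (RECN).

A plain MLP that maps the 20-bit binary code to a prediction of the
reconstruction residual, magnified tenfold.  Because the true residual of a
well-trained auto-encoder is small, training directly on it makes weight
updates tiny; scaling the label by 10 (and dividing the network output by 10
at compensation time) keeps the optimization well-conditioned without
changing what is learned.

Hidden widths 80 -> 140 -> 200 -> 260 -> 320 with ReLU, then a linear head
of width 320.  The RECN is trained after the auto-encoder is frozen, on
labels ``10 * (original - reconstruction)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import nn
from .bcae import CODE_BITS
from .synthetic import BEAT_LEN

__all__ = [
    "RECNSpec",
    "RESIDUAL_SCALE",
    "RECN",
    "build_recn",
    "residual_label",
    "compensate",
]

#: Fixed residual magnification factor.
RESIDUAL_SCALE = 10.0


@dataclass(frozen=True)
class RECNSpec:
    hidden_widths: Tuple[int, ...] = (80, 140, 200, 260, 320)
    hidden_activation: str = "relu"
    output_width: int = BEAT_LEN

    def __post_init__(self) -> None:
        if self.output_width != BEAT_LEN:
            raise ValueError(f"output width must be {BEAT_LEN}")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")


class RECN:
    """The MLP itself; shares the Layer forward/backward contract."""

    def __init__(self, layers: List[nn.Dense], spec: RECNSpec):
        self.layers = layers
        self.spec = spec

    def init_params(self, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)

    def forward(self, codes: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.asarray(codes, dtype=float)
        single = h.ndim == 1
        if single:
            h = h[None]
        if h.shape[1] != CODE_BITS:
            raise ValueError(f"RECN input must have {CODE_BITS} bits")
        for layer in self.layers:
            h = layer.forward(h, training)
        return h[0] if single else h

    def backward(self, grad: np.ndarray) -> None:
        g = np.asarray(grad)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        for layer in self.layers:
            for name, arr in layer.params().items():
                yield layer, name, arr


def build_recn(spec: RECNSpec = RECNSpec()) -> RECN:
    """Instantiate the MLP and validate the 20 -> ... -> 320 -> 320 trace."""
    expected = (80, 140, 200, 260, 320, BEAT_LEN)
    widths = tuple(spec.hidden_widths) + (spec.output_width,)
    if widths != expected:
        raise ValueError(f"RECN trace {widths} != expected {expected}")
    layers: List[nn.Dense] = []
    nin = CODE_BITS
    for i, w in enumerate(spec.hidden_widths):
        layers.append(nn.Dense(nin, w, activation=spec.hidden_activation, name=f"recn{i + 1}"))
        nin = w
    layers.append(nn.Dense(nin, spec.output_width, activation=None, name="recn_linear"))
    return RECN(layers, spec)


def residual_label(original: np.ndarray, bcae_output: np.ndarray) -> np.ndarray:
    """Training label: tenfold-magnified reconstruction residual."""
    o = np.asarray(original, dtype=float)
    r = np.asarray(bcae_output, dtype=float)
    if o.shape != r.shape:
        raise ValueError("original and reconstruction must have equal shapes")
    return RESIDUAL_SCALE * (o - r)


def compensate(bcae_output: np.ndarray, recn_output: np.ndarray) -> np.ndarray:
    """Refined reconstruction: auto-encoder output plus the scaled-back residual."""
    b = np.asarray(bcae_output, dtype=float)
    r = np.asarray(recn_output, dtype=float)
    if b.shape != r.shape:
        raise ValueError("reconstruction and residual must have equal shapes")
    return b + r / RESIDUAL_SCALE
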