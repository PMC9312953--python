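"""The binary convolutional auto-encoder.

The encoder maps a 320-sample normalized beat through nine tanh convolutions
interleaved with four max-poolings down to a 20-channel feature, and a final
hard-step binary encoding layer (BEL) turns it into 20 bits.  The decoder
mirrors this with nine transposed convolutions, four zero-padding
up-samplings and a closing affine layer that restores amplitude outside the
tanh range.  The fixed architecture trace is validated symbolically at build
time, so a mis-specified stack fails fast with the offending layer named.

The per-beat bit accounting is the whole point of the design: 320 samples x
11 bits in, 20 bits out of the bottleneck (plus a 10-bit interval code at the
packaging stage), i.e. a 117.33x compression ratio independent of content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .synthetic import BEAT_LEN

__all__ = [
    "LayerSpec",
    "BCAE",
    "default_bcae_spec",
    "build_bcae",
    "encode",
    "decode",
    "CODE_BITS",
]

CODE_BITS = 20

#: Expected symbolic traces (length, channels) after each layer; these are
#: the "Output Size" column of the reference architecture.
ENCODER_TRACE = [
    (320, 4), (320, 8), (160, 8), (160, 16), (160, 32), (80, 32), (80, 64),
    (80, 64), (40, 64), (40, 32), (40, 16), (20, 16), (20, 1), (20, 1),
]
DECODER_TRACE = [
    (20, 1), (40, 1), (40, 16), (40, 32), (80, 32), (80, 64), (80, 64),
    (160, 64), (160, 32), (160, 16), (320, 16), (320, 8), (320, 1), (320, 1),
]


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one stack entry."""

    kind: str  # conv | tconv | maxpool | upsample | binary_encoding | linear
    n_filters: int = 0
    kernel_size: int = 0
    pool_size: int = 2
    activation: Optional[str] = None
    batchnorm: bool = False
    dropout: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("conv", "tconv") and self.kernel_size < 1:
            raise ValueError(f"{self.kind} needs kernel_size >= 1")
        if self.kind in ("maxpool", "upsample") and self.pool_size < 1:
            raise ValueError(f"{self.kind} needs pool_size >= 1")


def default_bcae_spec() -> Tuple[List[LayerSpec], List[LayerSpec]]:
    """The reference architecture (encoder spec, decoder spec)."""
    c = lambda f, k, bn=True: LayerSpec("conv", f, k, activation="tanh", batchnorm=bn)
    t = lambda f, k, bn=True, dp=False: LayerSpec(
        "tconv", f, k, activation="tanh", batchnorm=bn, dropout=dp
    )
    encoder = [
        c(4, 8, bn=False),   # layer 1: no batch norm
        c(8, 32),
        LayerSpec("maxpool"),
        c(16, 64),
        c(32, 96),
        LayerSpec("maxpool"),
        c(64, 64),
        c(64, 32),
        LayerSpec("maxpool"),
        c(32, 16),
        c(16, 8),
        LayerSpec("maxpool"),
        c(1, 8),
        LayerSpec("binary_encoding"),
    ]
    decoder = [
        t(1, 8, bn=False),   # layer 15: no batch norm
        LayerSpec("upsample"),
        t(16, 8, dp=True),   # layer 17: dropout
        t(32, 16),
        LayerSpec("upsample"),
        t(64, 32),
        t(64, 64),
        LayerSpec("upsample"),
        t(32, 96, dp=True),  # layer 23: dropout
        t(16, 64),
        LayerSpec("upsample"),
        t(8, 32),
        t(1, 8),
        LayerSpec("linear"),
    ]
    return encoder, decoder


def _instantiate(
    specs: Sequence[LayerSpec], in_shape: Tuple[int, int], dropout_rate: float, tag: str
) -> Tuple[List[nn.Layer], List[Tuple[int, int]]]:
    layers: List[nn.Layer] = []
    trace: List[Tuple[int, int]] = []
    shape = in_shape
    for i, spec in enumerate(specs):
        name = f"{tag}{i + 1}"
        if spec.kind == "conv":
            layer = nn.Conv1D(shape[1], spec.n_filters, spec.kernel_size,
                              activation=spec.activation, batchnorm=spec.batchnorm,
                              name=name)
        elif spec.kind == "tconv":
            layer = nn.TConv1D(shape[1], spec.n_filters, spec.kernel_size,
                               activation=spec.activation, batchnorm=spec.batchnorm,
                               name=name)
        elif spec.kind == "maxpool":
            layer = nn.MaxPool(spec.pool_size, name=name)
        elif spec.kind == "upsample":
            layer = nn.UpsampleZero(spec.pool_size, name=name)
        elif spec.kind == "binary_encoding":
            layer = nn.BinaryEncoding(name=name)
        elif spec.kind == "linear":
            layer = _FlatLinear(shape[0] * shape[1], BEAT_LEN, name=name)
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
        shape = layer.output_shape(shape)
        layers.append(layer)
        trace.append(shape)
        if spec.dropout:
            drop = nn.Dropout(dropout_rate, name=name + "_dropout")
            layers.append(drop)
            trace.append(shape)
    return layers, trace


class _FlatLinear(nn.Dense):
    """Affine head operating on the flattened final feature map."""

    def __init__(self, in_features: int, out_features: int, name: str = ""):
        super().__init__(in_features, out_features, activation=None, name=name)
        self._in_shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        y = super().forward(flat, training)
        return y[:, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = super().backward(grad[:, :, 0])
        return g.reshape(self._in_shape)

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        if shape[0] * shape[1] != self.nin:
            raise ValueError(
                f"layer {self.name}: expected {self.nin} inputs, got {shape}"
            )
        return (self.nout, 1)


class BCAE:
    """Encoder + decoder with hand-written backprop through the bottleneck."""

    def __init__(
        self,
        encoder_layers: List[nn.Layer],
        decoder_layers: List[nn.Layer],
        encoder_spec: List[LayerSpec],
        decoder_spec: List[LayerSpec],
    ):
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.encoder_spec = encoder_spec
        self.decoder_spec = decoder_spec

    # -- parameter plumbing -------------------------------------------------

    def init_params(self, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.encoder_layers + self.decoder_layers:
            layer.init(rng)
            if isinstance(layer, nn.Dropout):
                layer.reseed(np.random.default_rng(rng.integers(2**31)))

    def layers(self) -> List[nn.Layer]:
        return self.encoder_layers + self.decoder_layers

    def parameters(self):
        """(layer, name, array) triples for every trainable/stat array."""
        for layer in self.layers():
            for name, arr in layer.params().items():
                yield layer, name, arr

    # -- forward / backward -------------------------------------------------

    def encode_batch(self, beats: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, 320) beats -> (B, 20) binary codes."""
        x = np.asarray(beats, dtype=float)
        if x.ndim == 1:
            x = x[None]
        if x.shape[1] != BEAT_LEN:
            raise ValueError(f"beats must have {BEAT_LEN} samples")
        h = x[:, :, None]
        for layer in self.encoder_layers:
            h = layer.forward(h, training)
        return h[:, :, 0]

    def decode_batch(self, codes: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, 20) codes -> (B, 320) reconstructions."""
        c = np.asarray(codes, dtype=float)
        if c.ndim == 1:
            c = c[None]
        if c.shape[1] != CODE_BITS:
            raise ValueError(f"codes must have {CODE_BITS} bits")
        h = c[:, :, None]
        for layer in self.decoder_layers:
            h = layer.forward(h, training)
        return h[:, :, 0]

    def forward(self, beats: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decode_batch(self.encode_batch(beats, training), training)

    def backward(self, grad_output: np.ndarray) -> None:
        """Backprop d(loss)/d(reconstruction) through decoder and encoder."""
        g = np.asarray(grad_output)[:, :, None]
        for layer in reversed(self.decoder_layers):
            g = layer.backward(g)
        for layer in reversed(self.encoder_layers):
            g = layer.backward(g)


def build_bcae(
    spec: Optional[Tuple[List[LayerSpec], List[LayerSpec]]] = None,
    dropout_rate: float = 0.25,
    expected_traces: Optional[Tuple[list, list]] = None,
) -> BCAE:
    """Instantiate the auto-encoder and validate its symbolic shape trace.

    By default the trace must reproduce the reference architecture exactly;
    any mismatch raises with the first offending layer named.
    """
    encoder_spec, decoder_spec = spec if spec is not None else default_bcae_spec()
    exp_enc, exp_dec = (
        expected_traces if expected_traces is not None else (ENCODER_TRACE, DECODER_TRACE)
    )
    enc_layers, enc_trace = _instantiate(encoder_spec, (BEAT_LEN, 1), dropout_rate, "enc")
    dec_layers, dec_trace = _instantiate(decoder_spec, (CODE_BITS, 1), dropout_rate, "dec")

    def check(trace, expected, layers, tag):
        # dropout entries repeat the preceding shape; drop them for comparison
        core = [s for s, layer in zip(trace, layers) if not isinstance(layer, nn.Dropout)]
        core_layers = [l for l in layers if not isinstance(l, nn.Dropout)]
        if len(core) != len(expected):
            raise ValueError(
                f"{tag}: expected {len(expected)} layers, spec produces {len(core)}"
            )
        for layer, got, want in zip(core_layers, core, expected):
            if tuple(got) != tuple(want):
                raise ValueError(
                    f"layer {layer.name}: output size {got} != expected {want}"
                )

    check(enc_trace, exp_enc, enc_layers, "encoder")
    check(dec_trace, exp_dec, dec_layers, "decoder")
    return BCAE(enc_layers, dec_layers, encoder_spec, decoder_spec)


def encode(beat: np.ndarray, model: BCAE) -> np.ndarray:
    """One 320-sample beat -> 20-bit binary code (inference mode)."""
    return model.encode_batch(np.asarray(beat, dtype=float)[None] if np.asarray(beat).ndim == 1 else beat)[0]


def decode(code: np.ndarray, model: BCAE) -> np.ndarray:
    """One 20-bit code -> 320-sample reconstruction (inference mode)."""
    c = np.asarray(code, dtype=float)
    return model.decode_batch(c[None] if c.ndim == 1 else c)[0]
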