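"""The seven network architectures for spectrum conversion and quantification.

Six sequence-to-sequence networks map a length-N low-field intensity vector
to its high-field counterpart: a densely connected autoencoder (DAE), a
convolutional autoencoder (CAE), a U-Net (CAE plus one skip connection at
the 32-channel depth), the same U-Net applied independently to contiguous
chunks (UNet-Chunks), a temporal convolutional network (TCN), and a chunked
encoder-only transformer.  A seventh network, a single-hidden-layer MLP,
regresses metabolite concentrations from a spectrum.

Conventions taken literally from the protocol this package implements:
convolutions use kernel 3, stride 1, padding 1 (no pooling, so channel count
is the only compression); hidden activations are ReLU; *output* layers are
linear, since targets contain negative noise excursions a ReLU could never
produce.  The transformer splits a spectrum into 46 contiguous chunks
treated as a token sequence, embeds each chunk linearly, applies encoder
layers without any positional encoding, and projects back per chunk.

Every architecture has a frozen spec dataclass that fully determines its
parameter count (in closed form, see ``param_count``) and — together with a
seed — its initial parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Conv1d,
    Dropout,
    Linear,
    Module,
    ReLU,
    Reshape,
    Sequential,
    TransformerEncoderLayer,
)
from .spectral_core import ValidationError

__all__ = [
    "ChunkScheme",
    "chunk_spectrum",
    "unchunk_spectrum",
    "DAESpec",
    "CAESpec",
    "UNetSpec",
    "TCNSpec",
    "TransformerSpec",
    "QuantMLPSpec",
    "ModelSpec",
    "build_dae",
    "build_cae",
    "build_unet",
    "build_tcn",
    "build_transformer",
    "build_quant_mlp",
    "build_model",
    "spec_from_json",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChunkScheme:
    """Contiguous partition of a spectrum into ``n_chunks`` x ``chunk_len``."""

    n_chunks: int = 46
    chunk_len: int = 1000

    def __post_init__(self) -> None:
        if self.n_chunks < 1 or self.chunk_len < 1:
            raise ValidationError("n_chunks and chunk_len must be positive")

    @property
    def total_len(self) -> int:
        return self.n_chunks * self.chunk_len


def chunk_spectrum(x: np.ndarray, scheme: ChunkScheme) -> np.ndarray:
    """Partition ``(L,)`` or ``(B, L)`` into chunks, order preserving.

    Returns ``(n_chunks, chunk_len)`` or ``(B, n_chunks, chunk_len)``.
    """
    x = np.asarray(x)
    if x.shape[-1] != scheme.total_len:
        raise ValidationError(
            f"spectrum length {x.shape[-1]} is not n_chunks x chunk_len = "
            f"{scheme.n_chunks} x {scheme.chunk_len} = {scheme.total_len}"
        )
    return x.reshape(x.shape[:-1] + (scheme.n_chunks, scheme.chunk_len))


def unchunk_spectrum(chunks: np.ndarray, scheme: ChunkScheme) -> np.ndarray:
    """Inverse of :func:`chunk_spectrum`: concatenate chunks back."""
    chunks = np.asarray(chunks)
    if chunks.shape[-2:] != (scheme.n_chunks, scheme.chunk_len):
        raise ValidationError(
            f"chunk array shape {chunks.shape} does not match scheme {scheme}"
        )
    return chunks.reshape(chunks.shape[:-2] + (scheme.total_len,))


# ---------------------------------------------------------------------------
# Architecture specs
# ---------------------------------------------------------------------------


def _dense_params(widths: Sequence[int]) -> int:
    return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


def _conv_params(c_in: int, c_out: int, kernel: int) -> int:
    return kernel * c_in * c_out + c_out


@dataclass(frozen=True)
class DAESpec:
    """Densely connected autoencoder: in -> hidden -> bottleneck and back."""

    input_len: int = 46_000
    hidden: int = 2_000
    bottleneck: int = 200
    seed: int = 0
    architecture: str = field(default="DAE", init=False)

    def __post_init__(self) -> None:
        if min(self.input_len, self.hidden, self.bottleneck) < 1:
            raise ValidationError("all DAE widths must be positive")

    def param_count(self) -> int:
        w = [self.input_len, self.hidden, self.bottleneck, self.hidden, self.input_len]
        return _dense_params(w)


@dataclass(frozen=True)
class CAESpec:
    """Convolutional autoencoder; encoder channels then the reciprocal."""

    input_len: int = 46_000
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    seed: int = 0
    architecture: str = field(default="CAE", init=False)

    def __post_init__(self) -> None:
        if not self.channels or min(self.channels) < 1:
            raise ValidationError("kernel counts must be positive")
        if self.kernel < 1:
            raise ValidationError("kernel size must be positive")

    def _channel_pairs(self) -> list[tuple[int, int]]:
        enc = [1, *self.channels]
        dec = [*reversed(self.channels), 1]
        pairs = list(zip(enc[:-1], enc[1:]))
        pairs += list(zip(dec[:-1], dec[1:]))
        return pairs

    def param_count(self) -> int:
        return sum(_conv_params(a, b, self.kernel) for a, b in self._channel_pairs())


@dataclass(frozen=True)
class UNetSpec:
    """CAE topology plus one skip connection at the 32-channel depth.

    The encoder activation of the ``skip_channels``-kernel layer is
    concatenated onto the input of the decoder layer producing
    ``skip_channels`` channels.  With ``chunked`` the network is applied
    independently to each chunk of the scheme.
    """

    input_len: int = 46_000
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    skip_channels: int = 32
    chunked: bool = False
    n_chunks: int = 46
    seed: int = 0
    architecture: str = field(default="UNET", init=False)

    def __post_init__(self) -> None:
        if not self.channels or min(self.channels) < 1:
            raise ValidationError("kernel counts must be positive")
        if self.skip_channels not in self.channels:
            raise ValidationError(
                f"skip_channels {self.skip_channels} not among encoder channels {self.channels}"
            )
        if self.chunked:
            if self.input_len % self.n_chunks != 0:
                raise ValidationError(
                    f"input_len {self.input_len} not divisible into {self.n_chunks} chunks"
                )
            object.__setattr__(self, "architecture", "UNET_CHUNKS")

    def param_count(self) -> int:
        enc = [1, *self.channels]
        dec = [*reversed(self.channels), 1]
        total = sum(_conv_params(a, b, self.kernel) for a, b in zip(enc[:-1], enc[1:]))
        skip_into = dec.index(self.skip_channels)  # decoder layer producing skip_channels
        for i, (a, b) in enumerate(zip(dec[:-1], dec[1:])):
            if i + 1 == skip_into:
                a = a + self.skip_channels  # concatenated skip input
            total += _conv_params(a, b, self.kernel)
        return total


@dataclass(frozen=True)
class TCNSpec:
    """Temporal convolutional network: residual blocks of two dilated causal
    convolutions each (dilations 1, 2, 4, ...), then a linear per-position
    projection to one channel."""

    input_len: int = 46_000
    channels: tuple[int, ...] = (25, 50, 100)
    kernel: int = 2
    dropout: float = 0.2
    seed: int = 0
    architecture: str = field(default="TCN", init=False)

    def __post_init__(self) -> None:
        if not self.channels or min(self.channels) < 1:
            raise ValidationError("channel counts must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")

    def receptive_field(self) -> int:
        """1 + 2 (k-1) sum(dilations): two convolutions per block."""
        return 1 + 2 * (self.kernel - 1) * sum(2 ** i for i in range(len(self.channels)))

    def param_count(self) -> int:
        total = 0
        c_prev = 1
        for c in self.channels:
            total += _conv_params(c_prev, c, self.kernel)  # conv1
            total += _conv_params(c, c, self.kernel)       # conv2
            if c_prev != c:
                total += _conv_params(c_prev, c, 1)        # residual 1x1
            c_prev = c
        total += c_prev * 1 + 1                             # linear projection
        return total


@dataclass(frozen=True)
class TransformerSpec:
    """Chunked encoder-only transformer with a linear chunk embedding,
    no positional encoding, and a linear per-chunk output head."""

    n_chunks: int = 46
    chunk_len: int = 1000
    d_model: int = 512
    n_layers: int = 6
    heads: int = 8
    ff: int = 2048
    dropout: float = 0.1
    seed: int = 0
    architecture: str = field(default="TRANSFORMER", init=False)

    def __post_init__(self) -> None:
        if self.d_model % self.heads != 0:
            raise ValidationError(
                f"embedding dim {self.d_model} not divisible by heads {self.heads}"
            )
        if min(self.n_chunks, self.chunk_len, self.d_model, self.n_layers,
               self.heads, self.ff) < 1:
            raise ValidationError("all transformer dimensions must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")

    @property
    def input_len(self) -> int:
        return self.n_chunks * self.chunk_len

    def scheme(self) -> ChunkScheme:
        return ChunkScheme(self.n_chunks, self.chunk_len)

    def param_count(self) -> int:
        d, f, c = self.d_model, self.ff, self.chunk_len
        per_layer = (d * 3 * d + 3 * d) + (d * d + d) + (d * f + f) + (f * d + d) + 4 * d
        return (c * d + d) + self.n_layers * per_layer + (d * c + c)


@dataclass(frozen=True)
class QuantMLPSpec:
    """Quantification MLP: spectrum -> hidden -> one output per metabolite (mM)."""

    input_len: int = 46_000
    hidden: int = 200
    n_outputs: int = 21
    seed: int = 0
    architecture: str = field(default="QUANT_MLP", init=False)

    def __post_init__(self) -> None:
        if self.n_outputs < 1:
            raise ValidationError(f"n_outputs must be >= 1, got {self.n_outputs}")
        if min(self.input_len, self.hidden) < 1:
            raise ValidationError("all MLP widths must be positive")

    def param_count(self) -> int:
        return _dense_params([self.input_len, self.hidden, self.n_outputs])


ModelSpec = DAESpec | CAESpec | UNetSpec | TCNSpec | TransformerSpec | QuantMLPSpec

_SPEC_CLASSES = {
    "DAE": DAESpec,
    "CAE": CAESpec,
    "UNET": UNetSpec,
    "UNET_CHUNKS": UNetSpec,
    "TCN": TCNSpec,
    "TRANSFORMER": TransformerSpec,
    "QUANT_MLP": QuantMLPSpec,
}


def spec_to_json(spec: ModelSpec) -> str:
    return json.dumps(asdict(spec), sort_keys=True)


def spec_from_json(text: str) -> ModelSpec:
    data = json.loads(text)
    arch = data.pop("architecture")
    cls = _SPEC_CLASSES[arch]
    if arch == "UNET_CHUNKS":
        data["chunked"] = True
    for key in ("channels",):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_dae(spec: DAESpec, dtype=None) -> Module:
    """Dense encoder in->hidden->bottleneck with the reciprocal decoder."""
    rng = np.random.default_rng(spec.seed)
    i, h, b = spec.input_len, spec.hidden, spec.bottleneck
    return Sequential(
        Linear(i, h, rng, dtype=dtype), ReLU(),
        Linear(h, b, rng, dtype=dtype), ReLU(),
        Linear(b, h, rng, dtype=dtype), ReLU(),
        Linear(h, i, rng, dtype=dtype),
    )


def build_cae(spec: CAESpec, dtype=None) -> Module:
    """Stride-1 convolutional autoencoder preserving spatial length."""
    rng = np.random.default_rng(spec.seed)
    pairs = spec._channel_pairs()
    layers: list[Module] = [Reshape((spec.input_len, 1))]
    for idx, (a, b) in enumerate(pairs):
        layers.append(Conv1d(a, b, spec.kernel, rng, padding="same", dtype=dtype))
        if idx < len(pairs) - 1:
            layers.append(ReLU())
    layers.append(Reshape((spec.input_len,)))
    return Sequential(*layers)


class _UNet(Module):
    """CAE with one skip connection: the encoder activation at the skip depth
    is concatenated onto the input of the decoder layer of the same width."""

    def __init__(self, spec: UNetSpec, dtype=None):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        k = spec.kernel
        enc_widths = [1, *spec.channels]
        self.enc = [
            Conv1d(a, b, k, rng, padding="same", dtype=dtype)
            for a, b in zip(enc_widths[:-1], enc_widths[1:])
        ]
        self.enc_relu = [ReLU() for _ in self.enc]
        self.skip_enc_index = list(spec.channels).index(spec.skip_channels)
        dec_widths = [*reversed(spec.channels), 1]
        self.skip_dec_index = dec_widths.index(spec.skip_channels)  # layer producing skip width
        self.dec: list[Conv1d] = []
        self.dec_relu: list[ReLU] = []
        for i, (a, b) in enumerate(zip(dec_widths[:-1], dec_widths[1:])):
            if i + 1 == self.skip_dec_index:
                a = a + spec.skip_channels
            self.dec.append(Conv1d(a, b, k, rng, padding="same", dtype=dtype))
            self.dec_relu.append(ReLU())

    def forward(self, x, train=False):
        B, L = x.shape
        h = x.reshape(B, L, 1)
        skip = None
        for i, (conv, relu) in enumerate(zip(self.enc, self.enc_relu)):
            h = relu.forward(conv.forward(h, train=train), train=train)
            if i == self.skip_enc_index:
                skip = h
        self._skip_width = skip.shape[-1]
        for i, conv in enumerate(self.dec):
            if i + 1 == self.skip_dec_index:
                h = np.concatenate([h, skip], axis=-1)
                self._concat_main_width = h.shape[-1] - self._skip_width
            h = conv.forward(h, train=train)
            if i < len(self.dec) - 1:
                h = self.dec_relu[i].forward(h, train=train)
        return h.reshape(B, L)

    def backward(self, grad):
        B, L = grad.shape
        g = grad.reshape(B, L, 1)
        g_skip = None
        for i in reversed(range(len(self.dec))):
            if i < len(self.dec) - 1:
                g = self.dec_relu[i].backward(g)
            g = self.dec[i].backward(g)
            if i + 1 == self.skip_dec_index:
                g, g_skip = (
                    g[..., : self._concat_main_width],
                    g[..., self._concat_main_width:],
                )
        for i in reversed(range(len(self.enc))):
            if i == self.skip_enc_index and g_skip is not None:
                g = g + g_skip
            g = self.enc[i].backward(self.enc_relu[i].backward(g))
        return g.reshape(B, L)


class _ChunkedWrapper(Module):
    """Apply an inner length-preserving network independently to each chunk."""

    def __init__(self, inner: Module, scheme: ChunkScheme):
        self.inner = inner
        self.scheme = scheme

    def forward(self, x, train=False):
        B, L = x.shape
        s = self.scheme
        xc = x.reshape(B * s.n_chunks, s.chunk_len)
        yc = self.inner.forward(xc, train=train)
        return yc.reshape(B, L)

    def backward(self, grad):
        B, L = grad.shape
        s = self.scheme
        g = grad.reshape(B * s.n_chunks, s.chunk_len)
        g = self.inner.backward(g)
        return g.reshape(B, L)


def build_unet(spec: UNetSpec, chunked: bool | None = None, dtype=None) -> Module:
    """U-Net builder; ``chunked`` overrides the spec flag when given."""
    if chunked is not None and chunked != spec.chunked:
        spec = UNetSpec(
            input_len=spec.input_len, channels=spec.channels, kernel=spec.kernel,
            skip_channels=spec.skip_channels, chunked=chunked,
            n_chunks=spec.n_chunks, seed=spec.seed,
        )
    if not spec.chunked:
        return _UNet(spec, dtype=dtype)
    chunk_len = spec.input_len // spec.n_chunks
    inner_spec = UNetSpec(
        input_len=chunk_len, channels=spec.channels, kernel=spec.kernel,
        skip_channels=spec.skip_channels, chunked=False, seed=spec.seed,
    )
    return _ChunkedWrapper(_UNet(inner_spec, dtype=dtype),
                           ChunkScheme(spec.n_chunks, chunk_len))


class _TemporalBlock(Module):
    """Residual block of two dilated causal convolutions (ReLU + dropout),
    with a 1x1 convolution on the shortcut when channel counts differ."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator, dtype=None):
        self.conv1 = Conv1d(c_in, c_out, kernel, rng, dilation=dilation,
                            padding="causal", dtype=dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.conv2 = Conv1d(c_out, c_out, kernel, rng, dilation=dilation,
                            padding="causal", dtype=dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.down = (
            Conv1d(c_in, c_out, 1, rng, padding="same", dtype=dtype)
            if c_in != c_out else None
        )
        self.out_relu = ReLU()

    def forward(self, x, train=False):
        h = self.drop1.forward(self.relu1.forward(self.conv1.forward(x, train=train),
                                                  train=train), train=train)
        h = self.drop2.forward(self.relu2.forward(self.conv2.forward(h, train=train),
                                                  train=train), train=train)
        res = x if self.down is None else self.down.forward(x, train=train)
        return self.out_relu.forward(h + res, train=train)

    def backward(self, grad):
        g = self.out_relu.backward(grad)
        g_res = g if self.down is None else self.down.backward(g)
        gh = self.conv2.backward(self.relu2.backward(self.drop2.backward(g)))
        gh = self.conv1.backward(self.relu1.backward(self.drop1.backward(gh)))
        return gh + g_res


class _TCN(Module):
    def __init__(self, spec: TCNSpec, dtype=None):
        rng = np.random.default_rng(spec.seed)
        self.blocks = []
        c_prev = 1
        for i, c in enumerate(spec.channels):
            self.blocks.append(
                _TemporalBlock(c_prev, c, spec.kernel, 2 ** i, spec.dropout, rng,
                               dtype=dtype)
            )
            c_prev = c
        self.head = Linear(c_prev, 1, rng, dtype=dtype)

    def forward(self, x, train=False):
        B, L = x.shape
        h = x.reshape(B, L, 1)
        for blk in self.blocks:
            h = blk.forward(h, train=train)
        return self.head.forward(h, train=train).reshape(B, L)

    def backward(self, grad):
        B, L = grad.shape
        g = self.head.backward(grad.reshape(B, L, 1))
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return g.reshape(B, L)


def build_tcn(spec: TCNSpec, dtype=None) -> Module:
    return _TCN(spec, dtype=dtype)


def build_transformer(spec: TransformerSpec, dtype=None) -> Module:
    """Chunk -> linear embed -> encoder stack (no positional encoding) ->
    linear per-chunk head -> unchunk."""
    rng = np.random.default_rng(spec.seed)
    layers: list[Module] = [
        Reshape((spec.n_chunks, spec.chunk_len)),
        Linear(spec.chunk_len, spec.d_model, rng, dtype=dtype),
    ]
    for _ in range(spec.n_layers):
        layers.append(
            TransformerEncoderLayer(spec.d_model, spec.heads, spec.ff, rng,
                                    p_drop=spec.dropout, dtype=dtype)
        )
    layers.append(Linear(spec.d_model, spec.chunk_len, rng, dtype=dtype))
    layers.append(Reshape((spec.input_len,)))
    return Sequential(*layers)


def build_quant_mlp(spec: QuantMLPSpec, dtype=None) -> Module:
    rng = np.random.default_rng(spec.seed)
    return Sequential(
        Linear(spec.input_len, spec.hidden, rng, dtype=dtype), ReLU(),
        Linear(spec.hidden, spec.n_outputs, rng, dtype=dtype),
    )


_BUILDERS = {
    "DAE": build_dae,
    "CAE": build_cae,
    "UNET": build_unet,
    "UNET_CHUNKS": build_unet,
    "TCN": build_tcn,
    "TRANSFORMER": build_transformer,
    "QUANT_MLP": build_quant_mlp,
}


def build_model(spec: ModelSpec, dtype=None) -> Module:
    """Build any architecture from its spec (deterministic in (spec, seed)).

    The returned module carries ``spec``, ``input_len`` and ``output_len``
    attributes so downstream pipelines can check dimensions up front.
    """
    model = _BUILDERS[spec.architecture](spec, dtype=dtype)
    model.spec = spec
    model.input_len = spec.input_len
    model.output_len = (
        spec.n_outputs if isinstance(spec, QuantMLPSpec) else spec.input_len
    )
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Module, spec: ModelSpec, path: str | Path) -> None:
    """Persist trained parameters with the self-describing spec JSON."""
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, spec_json=np.bytes_(spec_to_json(spec).encode()), **arrays)


def load_checkpoint(path: str | Path, dtype=None) -> tuple[Module, ModelSpec]:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        spec = spec_from_json(bytes(data["spec_json"]).decode())
        keys = sorted(k for k in data.files if k.startswith("param_"))
        arrays = [data[k] for k in keys]
    model = build_model(spec, dtype=dtype)
    model.load_state_arrays([a.astype(p.value.dtype) for a, p in
                             zip(arrays, model.parameters())])
    return model, spec
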