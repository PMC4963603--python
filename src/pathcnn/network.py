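"""The convolutional network over a shortest-dependency-path matrix.

Architecture
------------
Given the N x d matrix representation P of a fixed-length path, each of M
filters W_k (h x d) slides over the h-token windows of P with stride 1,
producing a feature map

    c_i = f( <W_k, P[i:i+h]> + b1_k ),   i = 1..N-h+1,

where <.,.> is the Frobenius inner product (the element-wise product of
filter and window, summed over all h*d entries) and f is tanh by default.
Max-over-time pooling keeps the single largest response of each map,
yielding a fixed-size vector r of M features regardless of path length.
A one-hidden-layer perceptron maps r to class confidences,

    O = f(W2 r + b2),    I = W3 O,    S = softmax(I),

with no bias on the confidence transform. C = 2 classes (interaction /
no interaction).

The dual-channel "combined" configuration runs two embedding channels
(typically one pretrained, one random) through channel-specific filter
banks and concatenates their pooled vectors, so r has 2M entries and W2
has 2M columns. Throughout this module P carries an explicit leading
channel axis: shape (n_channels, N, d).

Attribution: the window at which a filter's feature map attains its
maximum is the part of the path that filter responded to; the middle token
of that window is reported as the filter's key-word. Over a trained model
these are typically the interaction verbs and relation labels on the path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus_io import ValidationError
from .sdp import SdpSequence

__all__ = [
    "ACTIVATIONS",
    "ModelParams",
    "ForwardTrace",
    "init_params",
    "convolve",
    "max_pool",
    "forward",
    "forward_combined",
    "keywords",
]

N_CLASSES = 2

# name -> (f, f' as a function of the pre-activation)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(np.float64)),
}


@dataclass
class ModelParams:
    """All trainable network weights plus shape metadata.

    ``W`` holds the filter banks with an explicit channel axis,
    shape (n_channels, M, h, d); single-channel models have n_channels=1.
    ``W2`` is H x (n_channels*M), ``b2`` is H, ``W3`` is C x H. There is
    deliberately no bias on the confidence transform W3.
    """

    W: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    n_fixed: int
    activation: str = "tanh"

    def __post_init__(self) -> None:
        nch, M, h, d = self.W.shape
        if h > self.n_fixed:
            raise ValidationError(f"window size h={h} exceeds path length N={self.n_fixed}")
        if self.b1.shape != (nch, M):
            raise ValidationError(f"b1 shape {self.b1.shape} != {(nch, M)}")
        H = self.W2.shape[0]
        if self.W2.shape != (H, nch * M):
            raise ValidationError(f"W2 shape {self.W2.shape} != ({H}, {nch * M})")
        if self.b2.shape != (H,):
            raise ValidationError(f"b2 shape {self.b2.shape} != ({H},)")
        if self.W3.shape != (N_CLASSES, H):
            raise ValidationError(f"W3 shape {self.W3.shape} != ({N_CLASSES}, {H})")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        for name in ("W", "b1", "W2", "b2", "W3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite entries in {name}")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]

    @property
    def window(self) -> int:
        return self.W.shape[2]

    @property
    def dim(self) -> int:
        return self.W.shape[3]

    @property
    def hidden(self) -> int:
        return self.W2.shape[0]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b1": self.b1, "W2": self.W2, "b2": self.b2, "W3": self.W3}

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.W3.copy(), self.n_fixed, self.activation,
        )


@dataclass
class ForwardTrace:
    """All intermediates of one forward pass, kept for backprop/attribution."""

    P: np.ndarray                 # (nch, N, d)
    pre_maps: np.ndarray          # (nch, M, L) pre-activation feature maps
    feature_maps: np.ndarray      # (nch, M, L)
    pooled: np.ndarray            # (nch, M)
    argmax_positions: np.ndarray  # (nch, M), 0-based window index
    r: np.ndarray                 # (nch*M,)
    pre_hidden: np.ndarray        # (H,)
    O: np.ndarray                 # (H,)
    I: np.ndarray                 # (C,)
    S: np.ndarray                 # (C,)


def init_params(
    n_fixed: int,
    dim: int,
    window: int = 3,
    n_filters: int = 100,
    hidden: int = 500,
    n_channels: int = 1,
    activation: str = "tanh",
    seed: int = 0,
    init_scale: float = 0.05,
) -> ModelParams:
    """Uniform [-init_scale, init_scale] initialization of all weights."""
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-init_scale, init_scale, size=shape)
    return ModelParams(
        W=u(n_channels, n_filters, window, dim),
        b1=u(n_channels, n_filters),
        W2=u(hidden, n_channels * n_filters),
        b2=u(hidden),
        W3=u(N_CLASSES, hidden),
        n_fixed=n_fixed,
        activation=activation,
    )


def convolve(P: np.ndarray, W_k: np.ndarray, b1_k: float, f: Callable = np.tanh) -> np.ndarray:
    """Feature map of one filter over one (single-channel) path matrix.

    ``P`` is N x d, ``W_k`` is h x d; returns the length-(N-h+1) map with
    c_i = f(sum(W_k * P[i:i+h]) + b1_k), windows sliding with stride 1.
    """
    N, d = P.shape
    h, d2 = W_k.shape
    if d != d2:
        raise ValidationError(f"filter dim {d2} != path matrix dim {d}")
    if h > N:
        raise ValidationError(f"window size h={h} exceeds path length N={N}")
    windows = np.lib.stride_tricks.sliding_window_view(P, h, axis=0)  # (L, d, h)
    return f(np.einsum("ldh,hd->l", windows, W_k) + b1_k)


def max_pool(feature_map: np.ndarray) -> tuple[float, int]:
    """Max-over-time pooling: (maximum value, 0-based index of first max)."""
    fm = np.asarray(feature_map)
    if fm.size == 0:
        raise ValidationError("cannot pool an empty feature map")
    idx = int(np.argmax(fm))  # np.argmax returns the first maximum
    return float(fm[idx]), idx


def _softmax(I: np.ndarray) -> np.ndarray:
    # max-subtraction: the textbook exp(i_j)/sum(exp(i_k)) overflows for
    # large confidences
    z = I - np.max(I)
    e = np.exp(z)
    return e / e.sum()


def forward(P: np.ndarray, params: ModelParams) -> ForwardTrace:
    """Full forward pass. ``P`` has shape (n_channels, N, d)."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim == 2:
        P = P[None]
    nch, N, d = P.shape
    if nch != params.n_channels or d != params.dim:
        raise ValidationError(
            f"path matrix shape {P.shape} incompatible with model "
            f"({params.n_channels} channels, d={params.dim})"
        )
    f, _ = ACTIVATIONS[params.activation]
    h = params.window
    # (nch, L, d, h) -> windows as (nch, L, h, d)
    windows = np.lib.stride_tricks.sliding_window_view(P, h, axis=1)
    pre_maps = np.einsum("nldh,nmhd->nml", windows, params.W) + params.b1[:, :, None]
    feature_maps = f(pre_maps)
    argmax = np.argmax(feature_maps, axis=2)  # first max per filter
    pooled = np.take_along_axis(feature_maps, argmax[:, :, None], axis=2)[:, :, 0]
    r = pooled.reshape(-1)
    pre_hidden = params.W2 @ r + params.b2
    O = f(pre_hidden)
    I = params.W3 @ O
    if not np.all(np.isfinite(I)):
        raise FloatingPointError("non-finite values at the confidence layer")
    S = _softmax(I)
    return ForwardTrace(P, pre_maps, feature_maps, pooled, argmax, r, pre_hidden, O, I, S)


def forward_combined(P_pre: np.ndarray, P_rand: np.ndarray, params: ModelParams) -> ForwardTrace:
    """Dual-channel forward: pretrained and random channels, pooled vectors
    concatenated. Thin wrapper over :func:`forward` with a stacked P."""
    if params.n_channels != 2:
        raise ValidationError("forward_combined requires a 2-channel model")
    if P_pre.shape != P_rand.shape:
        raise ValidationError(
            f"channel shapes differ: {P_pre.shape} vs {P_rand.shape}"
        )
    return forward(np.stack([P_pre, P_rand]), params)


def keywords(trace: ForwardTrace, seq: SdpSequence | Sequence[str], window: int | None = None) -> list[str]:
    """Key-word of every filter: the middle token of its argmax window.

    Each filter contributes exactly the window where its feature map peaks;
    walking back from the pooled value through that window identifies the
    token the filter detected. For a 2-channel model the list has 2M
    entries (channel 0 filters first). ``PADDING`` results are reported
    as-is. Window sizes should be odd so the middle is well defined; for
    even h the token at position argmax + h/2 - 1 is used.
    """
    tokens = seq.tokens if isinstance(seq, SdpSequence) else tuple(seq)
    nch, M, L = trace.feature_maps.shape
    if window is None:
        window = len(tokens) - L + 1
    if window % 2 == 1:
        mid = (window - 1) // 2
    else:
        logging.getLogger(__name__).warning(
            "even window size %d: key-word taken left of window center", window
        )
        mid = window // 2 - 1
    out: list[str] = []
    for c in range(nch):
        for m in range(M):
            out.append(tokens[int(trace.argmax_positions[c, m]) + mid])
    return out
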