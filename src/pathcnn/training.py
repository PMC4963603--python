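"""Loss, exact backpropagation, and Adadelta updates.

Training minimizes the negative log-likelihood -log p(y|x) of the gold
label under the softmax output, one stochastic update per training pair
(no mini-batching). A fixed learning rate makes the loss unstable on this
architecture, so updates use Adadelta, which rescales each coordinate by
the ratio of its running RMS update magnitude to its running RMS gradient
magnitude:

    E[g^2]  <- rho E[g^2]  + (1-rho) g^2
    delta    = - sqrt(E[dx^2] + eps) / sqrt(E[g^2] + eps) * g
    E[dx^2] <- rho E[dx^2] + (1-rho) delta^2
    theta   <- theta + delta

with rho = 0.95 and eps = 1e-6 by default. Gradients are computed by the
chain rule through the whole network; max-pooling routes gradient only to
each filter's argmax window, and optionally into the embedding rows of the
tokens that occur in the window (the "update" embedding variants). The
PADDING row never receives gradient.

All arithmetic is float64: the analytic gradients are validated against
central finite differences, which needs the headroom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import ValidationError
from .embeddings import EmbeddingTable
from .network import ACTIVATIONS, ForwardTrace, ModelParams, forward

__all__ = [
    "TrainingConfig",
    "AdadeltaState",
    "Gradients",
    "nll",
    "backward",
    "embedding_gradient",
    "adadelta_step",
    "fit_network",
    "gradient_check",
    "train",
]

LOSS_CLAMP = 1e-12
VARIANTS = ("random", "random_update", "pretrained", "combined")


@dataclass
class TrainingConfig:
    """Optimization settings; defaults follow Zeiler's published Adadelta."""

    epochs: int = 100
    seed: int = 0
    rho: float = 0.95
    eps: float = 1e-6
    shuffle: bool = True
    trainable_embeddings: bool = False
    variant: str = "random"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if not (0.0 < self.rho < 1.0):
            raise ValidationError(f"rho must be in (0, 1), got {self.rho}")
        if self.eps <= 0:
            raise ValidationError(f"eps must be > 0, got {self.eps}")
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


@dataclass
class AdadeltaState:
    """Per-parameter running accumulators E[g^2] and E[dx^2]."""

    Eg2: dict[str, np.ndarray] = field(default_factory=dict)
    Edx2: dict[str, np.ndarray] = field(default_factory=dict)

    def ensure(self, name: str, like: np.ndarray) -> None:
        if name not in self.Eg2:
            self.Eg2[name] = np.zeros_like(like)
            self.Edx2[name] = np.zeros_like(like)


@dataclass
class Gradients:
    """Gradient of the per-example loss; shapes mirror ModelParams.

    ``dP`` is the gradient w.r.t. the input path matrix (n_channels, N, d),
    from which embedding-row gradients are scattered when embeddings are
    trainable.
    """

    dW: np.ndarray
    db1: np.ndarray
    dW2: np.ndarray
    db2: np.ndarray
    dW3: np.ndarray
    dP: np.ndarray

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b1": self.db1, "W2": self.dW2, "b2": self.db2, "W3": self.dW3}


def nll(S: np.ndarray, y: int) -> float:
    """Negative log-likelihood -log S[y], with S clamped at 1e-12."""
    if y not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {y}")
    return float(-np.log(max(float(S[y]), LOSS_CLAMP)))


def backward(trace: ForwardTrace, y: int, params: ModelParams) -> Gradients:
    """Exact gradient of the NLL loss w.r.t. every network parameter."""
    _, dfd = ACTIVATIONS[params.activation]
    nch, M, _ = trace.feature_maps.shape
    h = params.window

    dI = trace.S.copy()
    dI[y] -= 1.0                      # softmax + NLL
    dW3 = np.outer(dI, trace.O)
    dO = params.W3.T @ dI
    dpre2 = dO * dfd(trace.pre_hidden)
    dW2 = np.outer(dpre2, trace.r)
    db2 = dpre2
    dr = (params.W2.T @ dpre2).reshape(nch, M)

    # pooling routes gradient only to the argmax window of each filter
    pos = trace.argmax_positions                       # (nch, M)
    pre_at_max = np.take_along_axis(trace.pre_maps, pos[:, :, None], axis=2)[:, :, 0]
    dpre1 = dr * dfd(pre_at_max)                       # (nch, M)
    db1 = dpre1

    windows = np.lib.stride_tricks.sliding_window_view(trace.P, h, axis=1)  # (nch,L,d,h)
    dW = np.empty_like(params.W)
    dP = np.zeros_like(trace.P)
    offsets = np.arange(h)
    for c in range(nch):
        sel = windows[c, pos[c]]                       # (M, d, h)
        dW[c] = dpre1[c][:, None, None] * np.transpose(sel, (0, 2, 1))
        contrib = dpre1[c][:, None, None] * params.W[c]  # (M, h, d)
        np.add.at(dP[c], pos[c][:, None] + offsets[None, :], contrib)
    return Gradients(dW, db1, dW2, db2, dW3, dP)


def embedding_gradient(
    dP_channel: np.ndarray, tokens: Sequence[str], table: EmbeddingTable
) -> np.ndarray:
    """Scatter per-position gradients onto embedding rows.

    Rows of tokens absent from the vocabulary are dropped; the PADDING row
    is forced to zero (it is frozen by construction).
    """
    dD = np.zeros_like(table.D)
    rows = np.array([table.vocab.get(tok, -1) for tok in tokens])
    ok = rows >= 0
    np.add.at(dD, rows[ok], dP_channel[ok])
    dD[table.padding_row] = 0.0
    return dD


def adadelta_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdadeltaState,
    rho: float = 0.95,
    eps: float = 1e-6,
) -> None:
    """One in-place Adadelta update over a dict of parameter arrays."""
    for name, theta in params.items():
        g = grads[name]
        state.ensure(name, theta)
        Eg2, Edx2 = state.Eg2[name], state.Edx2[name]
        Eg2 *= rho
        Eg2 += (1.0 - rho) * g * g
        delta = -np.sqrt(Edx2 + eps) / np.sqrt(Eg2 + eps) * g
        Edx2 *= rho
        Edx2 += (1.0 - rho) * delta * delta
        theta += delta


def fit_network(
    token_seqs: Sequence[Sequence[str]],
    labels: Sequence[int],
    tables: list[EmbeddingTable],
    params: ModelParams,
    config: TrainingConfig,
) -> tuple[list[float], list[float]]:
    """Stochastic per-example training loop; updates params (and trainable
    embedding tables) in place. Returns per-epoch mean loss and accuracy."""
    n = len(token_seqs)
    if n == 0:
        raise ValidationError("empty training set")
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be in {0, 1}")
    if len(set(y.tolist())) == 1:
        import logging

        logging.getLogger(__name__).warning("training set contains a single class")

    # fixed vocabulary: precompute row indices once per channel
    rows_per_channel = [
        [np.array([tbl.vocab[tok] for tok in toks]) for toks in token_seqs]
        for tbl in tables
    ]
    rng = np.random.default_rng(config.seed)
    state = AdadeltaState()
    loss_log: list[float] = []
    acc_log: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = np.empty(n)
        correct = 0
        for j, i in enumerate(order):
            P = np.stack([tables[c].D[rows_per_channel[c][i]] for c in range(len(tables))])
            trace = forward(P, params)
            losses[j] = nll(trace.S, int(y[i]))
            correct += int(np.argmax(trace.S)) == int(y[i])
            grads = backward(trace, int(y[i]), params)
            pdict = params.arrays()
            gdict = grads.arrays()
            for c, tbl in enumerate(tables):
                if tbl.trainable:
                    pdict[f"D{c}"] = tbl.D
                    gdict[f"D{c}"] = embedding_gradient(grads.dP[c], token_seqs[i], tbl)
            adadelta_step(pdict, gdict, state, config.rho, config.eps)
        loss_log.append(float(losses.mean()))
        acc_log.append(correct / n)
    return loss_log, acc_log


def gradient_check(
    params: ModelParams,
    tables: list[EmbeddingTable],
    tokens: Sequence[str],
    y: int,
    step: float = 1e-5,
) -> float:
    """Compare analytic gradients with central finite differences.

    Perturbs every coordinate of every parameter array (and of every
    trainable embedding table) by +/- step and returns the maximum
    relative error |analytic - numeric| / max(1, |analytic|, |numeric|).
    """
    rows = [np.array([tbl.vocab[tok] for tok in tokens]) for tbl in tables]

    def loss() -> float:
        P = np.stack([tables[c].D[rows[c]] for c in range(len(tables))])
        trace = forward(P, params)
        return nll(trace.S, y)

    P = np.stack([tables[c].D[rows[c]] for c in range(len(tables))])
    trace = forward(P, params)
    grads = backward(trace, y, params)
    analytic = grads.arrays()
    targets: list[tuple[np.ndarray, np.ndarray]] = [
        (params.arrays()[name], analytic[name]) for name in analytic
    ]
    for c, tbl in enumerate(tables):
        if tbl.trainable:
            targets.append((tbl.D, embedding_gradient(grads.dP[c], tokens, tbl)))

    worst = 0.0
    for theta, g in targets:
        flat = theta.reshape(-1)
        gflat = g.reshape(-1)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + step
            lp = loss()
            flat[k] = orig - step
            lm = loss()
            flat[k] = orig
            numeric = (lp - lm) / (2.0 * step)
            err = abs(gflat[k] - numeric) / max(1.0, abs(gflat[k]), abs(numeric))
            worst = max(worst, err)
    return worst


def train(instances, parses, config: TrainingConfig | None = None, **estimator_kwargs):
    """Train a classifier from parses + instances (thin estimator wrapper)."""
    from .estimator import PathCNNClassifier
    from .sdp import extract_sequences

    config = config or TrainingConfig()
    kwargs = dict(
        variant=config.variant,
        epochs=config.epochs,
        rho=config.rho,
        eps=config.eps,
        shuffle=config.shuffle,
        trainable_embeddings=config.trainable_embeddings or None,
        seed=config.seed,
    )
    kwargs.update(estimator_kwargs)  # explicit estimator settings win
    clf = PathCNNClassifier(**kwargs)
    seqs = extract_sequences(parses, instances)
    clf.fit([s.tokens for s in seqs], [inst.label for inst in instances])
    return clf
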