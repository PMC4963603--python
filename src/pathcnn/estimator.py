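"""`PathCNNClassifier`: a scikit-learn style estimator for PPI extraction.

The estimator consumes serialized shortest-dependency-path token sequences
(lists of strings, as produced by :mod:`pathcnn.sdp`) and a binary label
per sequence, and learns a convolutional classifier over embedded paths.

Four embedding configurations are supported via ``variant``:

* ``"random"`` — randomly initialized embeddings, frozen during training;
* ``"random_update"`` — randomly initialized, fine-tuned during training;
* ``"pretrained"`` — pretrained vectors where available (random for
  out-of-vocabulary words and relation labels), frozen;
* ``"combined"`` — two channels, one pretrained (frozen) and one random
  (fine-tuned); their pooled feature vectors are concatenated.

Example
-------
>>> from pathcnn import PathCNNClassifier, synthetic
>>> parses, instances = synthetic.generate(synthetic.SynthConfig(n_instances=60, seed=0))
>>> from pathcnn.sdp import extract_sequences
>>> X = [s.tokens for s in extract_sequences(parses, instances)]
>>> y = [i.label for i in instances]
>>> clf = PathCNNClassifier(n_fixed=15, dim=20, n_filters=8, hidden=16,
...                         epochs=30, seed=0).fit(X, y)
>>> clf.score(X, y)  # doctest: +SKIP
1.0
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._seeds import derive_seed
from .corpus_io import ValidationError
from .embeddings import EmbeddingTable, build_table, lookup
from .network import ModelParams, forward, init_params, keywords
from .sdp import RESERVED_TOKENS, SdpSequence, fit_length
from .training import TrainingConfig, fit_network

__all__ = ["PathCNNClassifier"]


class PathCNNClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional classifier over shortest dependency paths.

    Parameters
    ----------
    n_fixed : int, default 20
        Fixed path length N; shorter paths are padded with ``PADDING``,
        longer ones truncated (see ``truncate``).
    dim : int, default 300
        Embedding dimension d.
    window : int, default 3
        Convolution window h (tokens per filter application). Odd values
        keep the key-word attribution well defined.
    n_filters : int, default 100
        Number of filters M per channel.
    hidden : int, default 500
        Hidden-layer width H of the classifier MLP.
    activation : str, default "tanh"
        Nonlinearity for convolution and hidden layer.
    variant : str, default "random"
        Embedding configuration; one of ``random``, ``random_update``,
        ``pretrained``, ``combined``.
    pretrained : mapping word -> vector, optional
        Pretrained embedding vectors (required for the ``pretrained`` and
        ``combined`` variants).
    trainable_embeddings : bool or None, default None
        Override embedding trainability; ``None`` derives it from the
        variant (True only for ``random_update`` and, on the random
        channel, ``combined``).
    init_range : float, default 0.25
        Half-range a of the uniform embedding initialization when no
        pretrained vectors are given; with pretrained vectors, a is the
        standard deviation of all pretrained entries.
    weight_init : float, default 0.05
        Half-range of the uniform network weight initialization.
    epochs, rho, eps, shuffle
        Training-loop settings (per-example Adadelta; see
        :mod:`pathcnn.training`).
    truncate : {"middle", "tail"}, default "middle"
        Truncation strategy for over-length paths.
    seed : int, default 0
        Master seed; per-stage seeds are derived from it.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    vocab_ : dict mapping token to embedding row (channel 0)
    tables_ : list of EmbeddingTable, one per channel
    params_ : ModelParams, the trained network weights
    loss_history_, accuracy_history_ : per-epoch training curves
    """

    _VARIANTS = ("random", "random_update", "pretrained", "combined")

    def __init__(
        self,
        n_fixed: int = 20,
        dim: int = 300,
        window: int = 3,
        n_filters: int = 100,
        hidden: int = 500,
        activation: str = "tanh",
        variant: str = "random",
        pretrained: Mapping[str, np.ndarray] | None = None,
        trainable_embeddings: bool | None = None,
        init_range: float = 0.25,
        weight_init: float = 0.05,
        epochs: int = 100,
        rho: float = 0.95,
        eps: float = 1e-6,
        shuffle: bool = True,
        truncate: str = "middle",
        seed: int = 0,
    ):
        self.n_fixed = n_fixed
        self.dim = dim
        self.window = window
        self.n_filters = n_filters
        self.hidden = hidden
        self.activation = activation
        self.variant = variant
        self.pretrained = pretrained
        self.trainable_embeddings = trainable_embeddings
        self.init_range = init_range
        self.weight_init = weight_init
        self.epochs = epochs
        self.rho = rho
        self.eps = eps
        self.shuffle = shuffle
        self.truncate = truncate
        self.seed = seed

    # ------------------------------------------------------------------

    def _prepare(self, X) -> list[tuple[str, ...]]:
        seqs = []
        for x in X:
            if isinstance(x, SdpSequence):
                if x.fixed_length == self.n_fixed:
                    seqs.append(x.tokens)
                    continue
                if x.fixed_length is not None and x.fixed_length < x.raw_length:
                    raise ValidationError(
                        "cannot refit an already-truncated sequence to a different length"
                    )
                raw = SdpSequence(tuple(x.tokens[: x.raw_length]), raw_length=x.raw_length)
                seqs.append(fit_length(raw, self.n_fixed, self.truncate).tokens)
            else:
                toks = tuple(x)
                seqs.append(
                    fit_length(
                        SdpSequence(toks, raw_length=len(toks)), self.n_fixed, self.truncate
                    ).tokens
                )
        return seqs

    def _build_tables(self, vocab_tokens: set[str]) -> list[EmbeddingTable]:
        if self.variant not in self._VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.variant in ("pretrained", "combined") and self.pretrained is None:
            raise ValidationError(f"variant {self.variant!r} requires pretrained vectors")
        emb_seed = derive_seed(self.seed, "embeddings")
        kw = dict(d=self.dim, a=self.init_range)
        if self.variant == "random":
            trainable = bool(self.trainable_embeddings)
            return [build_table(vocab_tokens, seed=emb_seed, trainable=trainable, **kw)]
        if self.variant == "random_update":
            trainable = True if self.trainable_embeddings is None else bool(self.trainable_embeddings)
            return [build_table(vocab_tokens, seed=emb_seed, trainable=trainable, **kw)]
        if self.variant == "pretrained":
            trainable = bool(self.trainable_embeddings)
            return [
                build_table(vocab_tokens, seed=emb_seed,
                            pretrained_records=self.pretrained, trainable=trainable, **kw)
            ]
        # combined: frozen pretrained channel + fine-tuned random channel
        rand_trainable = True if self.trainable_embeddings is None else bool(self.trainable_embeddings)
        return [
            build_table(vocab_tokens, seed=emb_seed,
                        pretrained_records=self.pretrained, trainable=False, **kw),
            build_table(vocab_tokens, seed=derive_seed(self.seed, "embeddings-rand"),
                        trainable=rand_trainable, **kw),
        ]

    # ------------------------------------------------------------------

    def fit(self, X, y):
        """Fit the network on token sequences ``X`` and binary labels ``y``.

        The vocabulary and all embedding rows are built from ``X`` only;
        tokens first seen at predict time are mapped to stable random
        vectors without entering the table.
        """
        seqs = self._prepare(X)
        y = np.asarray(y, dtype=int)
        if len(seqs) != len(y):
            raise ValidationError(f"X has {len(seqs)} sequences but y has {len(y)} labels")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        vocab_tokens = {tok for toks in seqs for tok in toks} | set(RESERVED_TOKENS)
        self.tables_ = self._build_tables(vocab_tokens)
        self.vocab_ = self.tables_[0].vocab
        self.params_ = init_params(
            n_fixed=self.n_fixed,
            dim=self.dim,
            window=self.window,
            n_filters=self.n_filters,
            hidden=self.hidden,
            n_channels=len(self.tables_),
            activation=self.activation,
            seed=derive_seed(self.seed, "weights"),
            init_scale=self.weight_init,
        )
        config = TrainingConfig(
            epochs=self.epochs,
            seed=derive_seed(self.seed, "shuffle"),
            rho=self.rho,
            eps=self.eps,
            shuffle=self.shuffle,
            variant=self.variant,
        )
        self.loss_history_, self.accuracy_history_ = fit_network(
            seqs, y, self.tables_, self.params_, config
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise ValidationError("estimator is not fitted; call fit first")

    def _traces(self, X):
        self._check_fitted()
        for toks in self._prepare(X):
            P = np.stack([lookup(toks, tbl) for tbl in self.tables_])
            yield toks, forward(P, self.params_)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, shape (n_instances, 2)."""
        return np.array([trace.S for _, trace in self._traces(X)])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def decision_function(self, X) -> np.ndarray:
        """Confidence margin I[1] - I[0] of the pre-softmax layer."""
        return np.array([trace.I[1] - trace.I[0] for _, trace in self._traces(X)])

    def key_words(self, X) -> list[list[str]]:
        """Per-instance key-words: for each filter, the middle token of the
        window where its feature map peaks (M per channel)."""
        return [keywords(trace, toks, self.window) for toks, trace in self._traces(X)]

    # ------------------------------------------------------------------
    # persistence

    def to_dict(self) -> dict:
        self._check_fitted()
        p = self.params_
        hyper = {
            "n_fixed": self.n_fixed, "dim": self.dim, "window": self.window,
            "n_filters": self.n_filters, "hidden": self.hidden,
            "n_channels": p.n_channels, "n_classes": 2,
        }
        return {
            "hyperparams": hyper,
            "activation": p.activation,
            "variant": self.variant,
            "truncate": self.truncate,
            "seed": self.seed,
            "params": {k: v.tolist() for k, v in p.arrays().items()},
            "tables": [t.to_dict() for t in self.tables_],
            "loss_history": list(self.loss_history_),
            "accuracy_history": list(self.accuracy_history_),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PathCNNClassifier":
        hyper = obj["hyperparams"]
        arrays = {k: np.asarray(v, dtype=np.float64) for k, v in obj["params"].items()}
        expect = {
            "W": (hyper["n_channels"], hyper["n_filters"], hyper["window"], hyper["dim"]),
            "b1": (hyper["n_channels"], hyper["n_filters"]),
            "W2": (hyper["hidden"], hyper["n_channels"] * hyper["n_filters"]),
            "b2": (hyper["hidden"],),
            "W3": (hyper["n_classes"], hyper["hidden"]),
        }
        for name, shape in expect.items():
            if arrays[name].shape != shape:
                raise ValidationError(
                    f"stored array {name} has shape {arrays[name].shape}, "
                    f"hyperparameters declare {shape}"
                )
        clf = cls(
            n_fixed=hyper["n_fixed"], dim=hyper["dim"], window=hyper["window"],
            n_filters=hyper["n_filters"], hidden=hyper["hidden"],
            activation=obj["activation"], variant=obj["variant"],
            truncate=obj["truncate"], seed=obj["seed"],
        )
        clf.params_ = ModelParams(
            W=arrays["W"], b1=arrays["b1"], W2=arrays["W2"], b2=arrays["b2"],
            W3=arrays["W3"], n_fixed=hyper["n_fixed"], activation=obj["activation"],
        )
        clf.tables_ = [EmbeddingTable.from_dict(t) for t in obj["tables"]]
        clf.vocab_ = clf.tables_[0].vocab
        clf.classes_ = np.array([0, 1])
        clf.loss_history_ = list(obj["loss_history"])
        clf.accuracy_history_ = list(obj["accuracy_history"])
        return clf
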