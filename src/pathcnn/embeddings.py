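"""Vocabulary and embedding matrix handling.

The embedding table maps every corpus token (words, relation labels, and
the reserved symbols ``Protein1``/``Protein2``/``PADDING``) to a row of a
|V| x d matrix D. Rows are either copied from a pretrained word2vec file
or drawn i.i.d. uniform from [-a, a]. When pretrained vectors are present,
``a`` defaults to the standard deviation of all pretrained entries, so the
random rows match the scale of the pretrained ones. The ``PADDING`` row is
all zeros and never receives gradient.

Relation labels ("nsubj", "prep-of", ...) are ordinary vocabulary entries;
pretrained files essentially never contain them, so they are always
randomly initialized — a known error source of embedding-based relation
extraction that this package reproduces faithfully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seeds import derive_seed
from .corpus_io import EmbeddingFileRecord, ValidationError
from .sdp import PADDING, RESERVED_TOKENS, SdpSequence

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingTable", "build_table", "lookup"]

PROVENANCE_PRETRAINED = "pretrained"
PROVENANCE_RANDOM = "random"
PROVENANCE_RESERVED = "reserved"


@dataclass
class EmbeddingTable:
    """Vocabulary-to-vector map with per-row provenance and trainability."""

    vocab: dict[str, int]
    D: np.ndarray  # |V| x d, float64
    d: int
    a: float
    provenance: list[str]
    trainable: bool
    _unseen_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def padding_row(self) -> int:
        return self.vocab[PADDING]

    def vector(self, token: str) -> np.ndarray:
        """Embedding vector for a token.

        Tokens unseen at fit time get a fresh uniform [-a, a] row whose
        RNG seed is derived from the token string, so the assignment is
        stable across runs and processes; the table itself is not grown.
        """
        row = self.vocab.get(token)
        if row is not None:
            return self.D[row]
        cached = self._unseen_cache.get(token)
        if cached is None:
            logger.warning("token %r not in vocabulary; assigning stable random vector", token)
            rng = np.random.default_rng(derive_seed(0, f"unseen:{token}"))
            cached = rng.uniform(-self.a, self.a, size=self.d)
            self._unseen_cache[token] = cached
        return cached

    def to_dict(self) -> dict:
        words = sorted(self.vocab, key=self.vocab.get)
        return {
            "words": words,
            "D": self.D.tolist(),
            "d": self.d,
            "a": self.a,
            "provenance": list(self.provenance),
            "trainable": self.trainable,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "EmbeddingTable":
        D = np.asarray(obj["D"], dtype=np.float64)
        vocab = {w: i for i, w in enumerate(obj["words"])}
        if D.shape != (len(vocab), obj["d"]):
            raise ValidationError(
                f"stored embedding matrix shape {D.shape} does not match "
                f"vocabulary size {len(vocab)} x d={obj['d']}"
            )
        return cls(
            vocab=vocab,
            D=D,
            d=int(obj["d"]),
            a=float(obj["a"]),
            provenance=list(obj["provenance"]),
            trainable=bool(obj["trainable"]),
        )


def build_table(
    vocab_tokens: Iterable[str],
    d: int,
    seed: int,
    pretrained_records: Sequence[EmbeddingFileRecord] | Mapping[str, np.ndarray] | None = None,
    a: float = 0.25,
    trainable: bool = False,
) -> EmbeddingTable:
    """Build an embedding table for a vocabulary.

    Words found in ``pretrained_records`` receive the pretrained vector;
    all others (and, always, the reserved symbols) are drawn uniform
    [-a, a]. With pretrained records present, ``a`` is recomputed as the
    standard deviation of all pretrained entries. Row order is the sorted
    vocabulary plus the reserved symbols, independent of input iteration
    order; the same seed always yields a bit-identical table.
    """
    if d < 1:
        raise ValidationError(f"embedding dimension must be >= 1, got {d}")
    pre: dict[str, np.ndarray] = {}
    if pretrained_records is not None:
        if isinstance(pretrained_records, Mapping):
            items = pretrained_records.items()
        else:
            items = ((r.word, r.vector) for r in pretrained_records)
        for word, vec in items:
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (d,):
                raise ValidationError(
                    f"pretrained vector for {word!r} has dimension {vec.shape[0] if vec.ndim else '?'}, expected {d}"
                )
            pre.setdefault(word, vec)
        if pre:
            a = float(np.std(np.stack(list(pre.values()))))

    words = sorted(set(vocab_tokens) - set(RESERVED_TOKENS)) + list(RESERVED_TOKENS)
    vocab = {w: i for i, w in enumerate(words)}
    D = np.empty((len(words), d), dtype=np.float64)
    provenance: list[str] = []
    for w in words:
        if w == PADDING:
            D[vocab[w]] = 0.0
            provenance.append(PROVENANCE_RESERVED)
        elif w in pre:
            D[vocab[w]] = pre[w]
            provenance.append(PROVENANCE_PRETRAINED)
        else:
            # one independent draw per row keeps the table invariant to
            # vocabulary additions elsewhere in the alphabetical order
            row_rng = np.random.default_rng(derive_seed(seed, f"row:{w}"))
            D[vocab[w]] = row_rng.uniform(-a, a, size=d)
            provenance.append(
                PROVENANCE_RESERVED if w in RESERVED_TOKENS else PROVENANCE_RANDOM
            )
    return EmbeddingTable(vocab=vocab, D=D, d=d, a=a, provenance=provenance, trainable=trainable)


def lookup(seq: SdpSequence | Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Matrix representation P (N x d) of a fixed-length token sequence."""
    tokens = seq.tokens if isinstance(seq, SdpSequence) else seq
    P = np.empty((len(tokens), table.d), dtype=np.float64)
    for i, tok in enumerate(tokens):
        P[i] = table.vector(tok)
    return P
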