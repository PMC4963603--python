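"""Readers and writers for dependency parses, instances, embeddings and models.

Formats
-------
* Dependency parses: CoNLL-X / CoNLL-U style columns. Only the ID, FORM,
  HEAD and DEPREL columns are used; a 4-column ``ID FORM HEAD DEPREL``
  layout is also accepted. Blank lines separate sentences; a comment line
  ``# sent_id = X`` (or a bare ``# X``) names the sentence.
* Instances: JSON lines, one candidate protein pair per line with explicit
  1-based inclusive token spans.
* Embeddings: word2vec text and binary formats.
* Models: a versioned, self-describing JSON container (see
  :func:`save_model`).
"""

from __future__ import annotations

import json
import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "DependencyParse",
    "Instance",
    "EmbeddingFileRecord",
    "ParseError",
    "ValidationError",
    "read_parses",
    "write_parses",
    "read_instances",
    "write_instances",
    "read_word2vec",
    "write_word2vec",
    "save_model",
    "load_model",
]


class ParseError(ValueError):
    """A file could not be parsed (malformed line, truncated binary...)."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass(frozen=True)
class Token:
    """One token of a dependency parse.

    ``index`` and ``head`` are 1-based; ``head == 0`` marks the root.
    ``deprel`` is the dependency relation label to the governor, kept as an
    opaque string exactly as read (collapsed labels like ``prep-of`` or
    ``prep_of`` are single tokens here).
    """

    index: int
    form: str
    head: int
    deprel: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise ValidationError(f"head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise ValidationError(f"token {self.index} is its own head")
        if not self.deprel:
            raise ValidationError(f"token {self.index} has empty deprel")


@dataclass(frozen=True)
class DependencyParse:
    """A dependency-parsed sentence: contiguous 1..n tokens, connected."""

    sentence_id: str
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        indices = [t.index for t in self.tokens]
        if indices != list(range(1, n + 1)):
            raise ValidationError(
                f"sentence {self.sentence_id!r}: token indices not contiguous 1..{n}"
            )
        for t in self.tokens:
            if t.head > n:
                raise ValidationError(
                    f"sentence {self.sentence_id!r}: token {t.index} has head "
                    f"{t.head} outside 1..{n}"
                )
        if n > 1 and not self._connected():
            raise ValidationError(
                f"sentence {self.sentence_id!r}: dependency graph is disconnected"
            )

    def _connected(self) -> bool:
        # undirected head-dependent edges; root attachments carry no edge
        n = len(self.tokens)
        adj: list[list[int]] = [[] for _ in range(n + 1)]
        for t in self.tokens:
            if t.head > 0:
                adj[t.index].append(t.head)
                adj[t.head].append(t.index)
        seen = {1}
        stack = [1]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == n

    def __len__(self) -> int:
        return len(self.tokens)

    def form(self, index: int) -> str:
        return self.tokens[index - 1].form


@dataclass(frozen=True)
class Instance:
    """One candidate protein pair in one parsed sentence.

    Spans are inclusive 1-based ``(start, end)`` token ranges; ``label`` is
    1 for an annotated interaction, 0 otherwise.
    """

    instance_id: str
    sentence_id: str
    e1_span: tuple[int, int]
    e2_span: tuple[int, int]
    label: int

    def __post_init__(self) -> None:
        for name, (s, e) in (("e1", self.e1_span), ("e2", self.e2_span)):
            if s < 1 or e < s:
                raise ValidationError(
                    f"instance {self.instance_id!r}: invalid {name} span ({s}, {e})"
                )
        if self.e1_span == self.e2_span:
            raise ValidationError(
                f"instance {self.instance_id!r}: e1 and e2 spans are identical"
            )
        if self.label not in (0, 1):
            raise ValidationError(
                f"instance {self.instance_id!r}: label must be 0 or 1, got {self.label}"
            )


@dataclass(frozen=True)
class EmbeddingFileRecord:
    word: str
    vector: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# dependency parses


def read_parses(path: str | Path) -> list[DependencyParse]:
    """Read CoNLL-style dependency parses.

    Column layouts accepted per token line (whitespace separated):

    * >= 8 columns (CoNLL-X / CoNLL-U): ID FORM ... HEAD(col 7) DEPREL(col 8)
    * exactly 4 columns: ID FORM HEAD DEPREL

    Lines whose ID is not a plain integer (multi-word ranges ``1-2``, empty
    nodes ``1.1``) are skipped. Disconnected parses are rejected.
    """
    parses: list[DependencyParse] = []
    tokens: list[Token] = []
    sent_id: str | None = None
    n_sent = 0

    def flush() -> None:
        nonlocal tokens, sent_id, n_sent
        if tokens:
            sid = sent_id if sent_id is not None else f"s{n_sent}"
            parses.append(DependencyParse(sid, tuple(tokens)))
            n_sent += 1
        tokens = []
        sent_id = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                comment = line[1:].strip()
                if comment.startswith("sent_id"):
                    sent_id = comment.split("=", 1)[1].strip()
                elif sent_id is None and comment:
                    sent_id = comment
                continue
            cols = line.split()
            if len(cols) >= 8:
                idx_s, form, head_s, deprel = cols[0], cols[1], cols[6], cols[7]
            elif len(cols) == 4:
                idx_s, form, head_s, deprel = cols
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 or >=8 columns, got {len(cols)}"
                )
            if not idx_s.isdigit():
                if re.fullmatch(r"\d+[-.]\d+", idx_s):
                    continue  # multiword token or empty-node line
                raise ParseError(f"{path}:{lineno}: invalid token ID {idx_s!r}")
            try:
                head = int(head_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer head {head_s!r}") from exc
            try:
                tokens.append(Token(int(idx_s), form, head, deprel))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    flush()
    return parses


def write_parses(parses: Iterable[DependencyParse], path: str | Path) -> None:
    """Write parses in the 4-column ``ID FORM HEAD DEPREL`` layout."""
    with open(path, "w", encoding="utf-8") as fh:
        for parse in parses:
            fh.write(f"# sent_id = {parse.sentence_id}\n")
            for t in parse.tokens:
                fh.write(f"{t.index}\t{t.form}\t{t.head}\t{t.deprel}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# instances


def read_instances(
    path: str | Path,
    parses: Sequence[DependencyParse] | None = None,
) -> list[Instance]:
    """Read JSON-lines instances; optionally cross-check against parses."""
    by_id = {p.sentence_id: p for p in parses} if parses is not None else None
    instances: list[Instance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON") from exc
            try:
                inst = Instance(
                    instance_id=str(obj["instance_id"]),
                    sentence_id=str(obj["sentence_id"]),
                    e1_span=tuple(int(v) for v in obj["e1"]),
                    e2_span=tuple(int(v) for v in obj["e2"]),
                    label=int(obj["label"]),
                )
            except (KeyError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: missing/invalid field: {exc}") from exc
            if by_id is not None:
                if inst.sentence_id not in by_id:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown sentence_id {inst.sentence_id!r}"
                    )
                n = len(by_id[inst.sentence_id])
                for name, span in (("e1", inst.e1_span), ("e2", inst.e2_span)):
                    if span[1] > n:
                        raise ValidationError(
                            f"{path}:{lineno}: {name} span {span} outside sentence "
                            f"of {n} tokens"
                        )
            instances.append(inst)
    return instances


def write_instances(instances: Iterable[Instance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "instance_id": inst.instance_id,
                        "sentence_id": inst.sentence_id,
                        "e1": list(inst.e1_span),
                        "e2": list(inst.e2_span),
                        "label": inst.label,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# word2vec embeddings


def read_word2vec(path: str | Path, format: str = "text") -> list[EmbeddingFileRecord]:
    """Read a word2vec embedding file.

    ``format="text"``: header line ``count dim``, then ``word v1 ... vd``
    lines (vectors read as float64). ``format="binary"``: the standard
    word2vec binary layout (float32 vectors). Duplicate words keep the
    first occurrence; a warning is logged.
    """
    if format == "text":
        records = _read_w2v_text(path)
    elif format == "binary":
        records = _read_w2v_binary(path)
    else:
        raise ValueError(f"unknown embedding format {format!r}")
    seen: dict[str, int] = {}
    out: list[EmbeddingFileRecord] = []
    for rec in records:
        if rec.word in seen:
            logger.warning("duplicate embedding word %r: keeping first occurrence", rec.word)
            continue
        seen[rec.word] = len(out)
        out.append(rec)
    return out


def _read_w2v_text(path: str | Path) -> list[EmbeddingFileRecord]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: malformed word2vec text header")
        count, dim = int(header[0]), int(header[1])
        records = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            parts = [p for p in parts if p != ""]
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {dim} vector components, "
                    f"got {len(parts) - 1}"
                )
            vec = np.array([float(v) for v in parts[1:]], dtype=np.float64)
            records.append(EmbeddingFileRecord(parts[0], vec))
    if len(records) != count:
        raise ParseError(
            f"{path}: header declares {count} words but file has {len(records)}"
        )
    return records


def _read_w2v_binary(path: str | Path) -> list[EmbeddingFileRecord]:
    with open(path, "rb") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: malformed word2vec binary header")
        count, dim = int(header[0]), int(header[1])
        records = []
        for _ in range(count):
            word_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if ch == b"":
                    raise ParseError(f"{path}: truncated binary file in word")
                if ch == b" ":
                    break
                if ch != b"\n":
                    word_bytes.extend(ch)
            buf = fh.read(4 * dim)
            if len(buf) != 4 * dim:
                raise ParseError(f"{path}: truncated binary file in vector")
            vec = np.frombuffer(buf, dtype="<f4", count=dim).astype(np.float64)
            records.append(EmbeddingFileRecord(word_bytes.decode("utf-8"), vec))
    return records


def write_word2vec(
    records: Sequence[EmbeddingFileRecord], path: str | Path, format: str = "text"
) -> None:
    """Write word2vec embeddings.

    Text vectors are written with ``repr`` (shortest round-tripping
    decimal), so text read/write is lossless for float64. Binary vectors
    are float32, matching the standard layout.
    """
    if not records:
        dim = 0
    else:
        dim = len(records[0].vector)
        for rec in records:
            if len(rec.vector) != dim:
                raise ValidationError(
                    f"embedding dimension mismatch: {rec.word!r} has "
                    f"{len(rec.vector)}, expected {dim}"
                )
    if format == "text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(records)} {dim}\n")
            for rec in records:
                comps = " ".join(repr(float(v)) for v in rec.vector)
                fh.write(f"{rec.word} {comps}\n")
    elif format == "binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(records)} {dim}\n".encode("utf-8"))
            for rec in records:
                fh.write(rec.word.encode("utf-8") + b" ")
                fh.write(np.asarray(rec.vector, dtype="<f4").tobytes())
            _ = struct  # struct kept for symmetry with readers
    else:
        raise ValueError(f"unknown embedding format {format!r}")


# ---------------------------------------------------------------------------
# model container

MODEL_FORMAT = "pathcnn-model"
MODEL_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Save a fitted classifier to a versioned JSON container.

    Floats are serialized with their shortest round-tripping decimal form,
    so ``load_model(save_model(m))`` reproduces every weight bit-exactly.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "model": model.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path):
    from .estimator import PathCNNClassifier

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValidationError(f"{path}: not a {MODEL_FORMAT} container")
    if payload.get("version") != MODEL_VERSION:
        raise ValidationError(
            f"{path}: container version {payload.get('version')} != {MODEL_VERSION}"
        )
    return PathCNNClassifier.from_dict(payload["model"])
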