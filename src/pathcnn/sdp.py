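"""Shortest dependency path extraction, entity blinding and serialization.

The shortest dependency path (sdp) between two protein mentions is the
minimum-hop path over the sentence's head-dependent edges, viewed
undirected. The two mentions are blinded to the reserved symbols
``Protein1`` and ``Protein2`` and the path is serialized as an interleaved
word/relation token sequence, e.g.::

    Protein1 nsubj affects dobj properties prep-of Protein2

Relation labels are treated as ordinary tokens downstream. The sequence is
brought to a fixed length N by appending ``PADDING`` or by symmetric
interior truncation.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

from .corpus_io import DependencyParse, Instance, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PROTEIN1",
    "PROTEIN2",
    "PADDING",
    "RESERVED_TOKENS",
    "PathResult",
    "SdpSequence",
    "entity_head",
    "shortest_path",
    "serialize",
    "fit_length",
    "extract_sequence",
    "extract_sequences",
]

PROTEIN1 = "Protein1"
PROTEIN2 = "Protein2"
PADDING = "PADDING"
RESERVED_TOKENS = (PROTEIN1, PROTEIN2, PADDING)


@dataclass(frozen=True)
class PathResult:
    """An sdp as token indices plus the relation labels along it."""

    node_indices: tuple[int, ...]
    edge_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.edge_labels) != len(self.node_indices) - 1:
            raise ValidationError("edge count must be node count - 1")
        if len(set(self.node_indices)) != len(self.node_indices):
            raise ValidationError("path revisits a node")


@dataclass(frozen=True)
class SdpSequence:
    """Serialized, blinded sdp token sequence.

    ``raw_length`` is the token count before padding/truncation (always odd:
    k nodes interleaved with k-1 relations); ``fixed_length`` is set once
    :func:`fit_length` has been applied.
    """

    tokens: tuple[str, ...]
    raw_length: int
    fixed_length: int | None = None


def entity_head(parse: DependencyParse, span: tuple[int, int]) -> int:
    """Return the syntactic head token of a mention span.

    The head is the unique span token whose governor lies outside the span.
    Multi-headed or headless spans (possible with collapsed representations)
    fall back to the last span token, with a warning.
    """
    start, end = span
    if start < 1 or end > len(parse) or end < start:
        raise ValidationError(f"span ({start}, {end}) invalid for {len(parse)}-token sentence")
    inside = set(range(start, end + 1))
    candidates = [t.index for t in parse.tokens[start - 1 : end] if t.head not in inside]
    if len(candidates) == 1:
        return candidates[0]
    logger.warning(
        "span (%d, %d) in sentence %r has %d external-head tokens; using last token",
        start, end, parse.sentence_id, len(candidates),
    )
    return end


def shortest_path(parse: DependencyParse, u: int, v: int) -> PathResult:
    """Breadth-first shortest path between tokens ``u`` and ``v``.

    The dependency graph is undirected for path finding; neighbors are
    explored in ascending token index, which makes the returned path
    deterministic when several shortest paths exist.
    """
    n = len(parse)
    if u == v:
        raise ValidationError(f"degenerate pair: u == v == {u}")
    if not (1 <= u <= n and 1 <= v <= n):
        raise ValidationError(f"token indices ({u}, {v}) out of range 1..{n}")

    adj: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    label: dict[tuple[int, int], str] = {}
    for t in parse.tokens:
        if t.head > 0:
            adj[t.index].append(t.head)
            adj[t.head].append(t.index)
            label[(t.index, t.head)] = t.deprel
            label[(t.head, t.index)] = t.deprel
    for neighbors in adj.values():
        neighbors.sort()

    parent: dict[int, int] = {u: 0}
    queue: deque[int] = deque([u])
    while queue:
        cur = queue.popleft()
        if cur == v:
            break
        for nxt in adj[cur]:
            if nxt not in parent:
                parent[nxt] = cur
                queue.append(nxt)
    if v not in parent:
        raise ValidationError(
            f"tokens {u} and {v} are not connected in sentence {parse.sentence_id!r}"
        )

    nodes = [v]
    while nodes[-1] != u:
        nodes.append(parent[nodes[-1]])
    nodes.reverse()
    edges = tuple(label[(a, b)] for a, b in zip(nodes, nodes[1:]))
    return PathResult(tuple(nodes), edges)


def serialize(path_result: PathResult, parse: DependencyParse) -> SdpSequence:
    """Blind the endpoints and interleave words with relation labels.

    The first node becomes ``Protein1``, the last ``Protein2``; interior
    words are lowercased surface forms; relation labels are inserted
    verbatim between consecutive nodes. A k-node path yields 2k-1 tokens.
    """
    nodes = path_result.node_indices
    words = [PROTEIN1]
    words += [parse.form(i).lower() for i in nodes[1:-1]]
    words.append(PROTEIN2)
    tokens: list[str] = []
    for i, word in enumerate(words):
        tokens.append(word)
        if i < len(path_result.edge_labels):
            tokens.append(path_result.edge_labels[i])
    return SdpSequence(tuple(tokens), raw_length=len(tokens))


def fit_length(seq: SdpSequence, n_fixed: int, truncate: str = "middle") -> SdpSequence:
    """Pad with ``PADDING`` or truncate the sequence to exactly ``n_fixed``.

    ``truncate="middle"`` removes interior tokens symmetrically around the
    path midpoint, keeping both entity anchors and near-entity context;
    ``truncate="tail"`` keeps the first ``n_fixed - 1`` tokens plus the
    final ``Protein2``.
    """
    if n_fixed < 3:
        raise ValidationError(f"fixed length must be >= 3, got {n_fixed}")
    toks = list(seq.tokens)
    if len(toks) <= n_fixed:
        toks += [PADDING] * (n_fixed - len(toks))
    elif truncate == "middle":
        head = (n_fixed + 1) // 2
        tail = n_fixed - head
        toks = toks[:head] + toks[len(toks) - tail :]
    elif truncate == "tail":
        toks = toks[: n_fixed - 1] + [toks[-1]]
    else:
        raise ValidationError(f"unknown truncation strategy {truncate!r}")
    return SdpSequence(tuple(toks), raw_length=seq.raw_length, fixed_length=n_fixed)


def extract_sequence(
    parse: DependencyParse,
    instance: Instance,
    n_fixed: int | None = None,
    truncate: str = "middle",
) -> SdpSequence:
    """sdp extraction for one instance: head selection, BFS, blinding."""
    u = entity_head(parse, instance.e1_span)
    v = entity_head(parse, instance.e2_span)
    if u == v:
        raise ValidationError(
            f"instance {instance.instance_id!r}: entity spans share head token {u}"
        )
    seq = serialize(shortest_path(parse, u, v), parse)
    if n_fixed is not None:
        seq = fit_length(seq, n_fixed, truncate)
    return seq


def extract_sequences(parses, instances, n_fixed=None, truncate="middle"):
    """Extract sequences for many instances; parses keyed by sentence_id."""
    by_id = {p.sentence_id: p for p in parses}
    out = []
    for inst in instances:
        if inst.sentence_id not in by_id:
            raise ValidationError(
                f"instance {inst.instance_id!r}: unknown sentence {inst.sentence_id!r}"
            )
        out.append(extract_sequence(by_id[inst.sentence_id], inst, n_fixed, truncate))
    return out
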