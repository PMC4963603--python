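"""Synthetic PPI-style corpus generator.

Real sdp-based extraction rests on one structural fact: the shortest
dependency path between two interacting proteins almost always passes
through an interaction verb ("binds", "inhibits", ...). The generator
reproduces exactly that signal and nothing else: each sentence is a small
dependency tree whose path between the two (single-token) entity mentions
runs through a verb drawn from a positive trigger lexicon for label-1
instances and from a disjoint neutral lexicon for label-0 instances.
Distractor subtrees hang off the path but never contain trigger words, so
the label is conditionally independent of everything except the on-path
verb — a learner beating chance must be reading path content.

This is deliberately not linguistically realistic: no negation, no
coordination ambiguity, one candidate pair per sentence, and clean parses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .corpus_io import DependencyParse, Instance, Token, ValidationError

__all__ = ["SynthConfig", "generate", "worked_example", "TRIGGER_LEXICON", "NEUTRAL_LEXICON"]

TRIGGER_LEXICON = ("activates", "inhibits", "binds", "phosphorylates", "stimulates")
NEUTRAL_LEXICON = ("precedes", "accompanies", "resembles", "follows", "flanks")

_FILLER_NOUNS = ("complex", "domain", "pathway", "expression", "receptor",
                 "subunit", "region", "levels")
_DISTRACTOR_WORDS = ("the", "novel", "human", "recombinant", "putative", "cellular")
_PATH_RELATIONS = ("nsubj", "dobj", "prep-of", "amod", "conj")
_DISTRACTOR_RELATIONS = ("amod", "conj")


@dataclass
class SynthConfig:
    """Generator settings.

    ``path_length_distribution`` maps raw serialized path lengths (odd,
    >= 5 so an interior verb exists between the two entities) to
    probabilities. Defaults emulate short biomedical sdps: mostly 5-7
    tokens, occasionally longer.
    """

    n_instances: int = 100
    positive_fraction: float = 0.5
    trigger_lexicon: tuple[str, ...] = TRIGGER_LEXICON
    neutral_lexicon: tuple[str, ...] = NEUTRAL_LEXICON
    path_length_distribution: dict[int, float] = field(
        default_factory=lambda: {5: 0.35, 7: 0.35, 9: 0.2, 11: 0.1}
    )
    distractor_branches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValidationError("n_instances must be >= 1")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValidationError("positive_fraction must be in (0, 1)")
        if not self.trigger_lexicon or not self.neutral_lexicon:
            raise ValidationError("lexicons must be non-empty")
        if set(self.trigger_lexicon) & set(self.neutral_lexicon):
            raise ValidationError("trigger and neutral lexicons must be disjoint")
        if self.distractor_branches < 0:
            raise ValidationError("distractor_branches must be >= 0")
        total = 0.0
        for length, p in self.path_length_distribution.items():
            if length % 2 == 0 or length < 5:
                raise ValidationError(
                    f"raw path length must be odd and >= 5 (an interior verb is "
                    f"required between the entities), got {length}"
                )
            if p < 0:
                raise ValidationError("path length probabilities must be >= 0")
            total += p
        if not np.isclose(total, 1.0):
            raise ValidationError("path length probabilities must sum to 1")


def _make_sentence(
    rng: np.random.Generator, config: SynthConfig, label: int, idx: int
) -> tuple[DependencyParse, Instance]:
    lengths = sorted(config.path_length_distribution)
    probs = np.array([config.path_length_distribution[l] for l in lengths])
    raw_len = int(rng.choice(lengths, p=probs / probs.sum()))
    k = (raw_len + 1) // 2  # path nodes; k >= 3

    lexicon = config.trigger_lexicon if label == 1 else config.neutral_lexicon
    verb = str(rng.choice(lexicon))
    verb_pos = int(rng.integers(1, k - 1))  # interior position, 0-based

    words = [f"PROT{rng.integers(0, 500)}"]
    words += [str(rng.choice(_FILLER_NOUNS)) for _ in range(k - 2)]
    words.append(f"PROT{rng.integers(0, 500)}")
    words[verb_pos] = verb

    # Chain tree rooted at the verb: every path node points toward the verb.
    # All edge labels are drawn uniformly from the relation set, so the
    # on-path verb is the only token systematically tied to the label and
    # the planted signal stays identifiable for attribution tests.
    heads = [0] * k
    rels = [""] * k
    for i in range(k):
        if i < verb_pos:
            heads[i] = i + 2  # 1-based head = next node toward the verb
            rels[i] = str(rng.choice(_PATH_RELATIONS))
        elif i > verb_pos:
            heads[i] = i  # 1-based head = previous node
            rels[i] = str(rng.choice(_PATH_RELATIONS))
        else:
            heads[i] = 0
            rels[i] = "root"

    tokens = [Token(i + 1, words[i], heads[i], rels[i]) for i in range(k)]
    for _ in range(config.distractor_branches):
        attach = int(rng.integers(1, k + 1))
        tokens.append(
            Token(
                len(tokens) + 1,
                str(rng.choice(_DISTRACTOR_WORDS)),
                attach,
                str(rng.choice(_DISTRACTOR_RELATIONS)),
            )
        )

    sid = f"synth-{idx}"
    parse = DependencyParse(sid, tuple(tokens))
    instance = Instance(f"inst-{idx}", sid, (1, 1), (k, k), label)
    return parse, instance


def generate(config: SynthConfig) -> tuple[list[DependencyParse], list[Instance]]:
    """Generate a labeled synthetic corpus; deterministic under the seed.

    Exactly ``round(n_instances * positive_fraction)`` instances carry
    label 1, assigned to random positions in the corpus.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "synth"))
    n_pos = round(config.n_instances * config.positive_fraction)
    labels = np.zeros(config.n_instances, dtype=int)
    labels[rng.choice(config.n_instances, size=n_pos, replace=False)] = 1
    parses, instances = [], []
    for idx, label in enumerate(labels):
        parse, inst = _make_sentence(rng, config, int(label), idx)
        parses.append(parse)
        instances.append(inst)
    return parses, instances


def worked_example() -> tuple[DependencyParse, Instance]:
    """Hand-transcribed parse of the sentence

        "Acanthamoeba profilin affects the mechanical properties of
        non-filamentous actin."

    with collapsed prepositions: "actin" attaches to "properties" through
    the single relation ``prep-of`` and the function word "of" hangs off
    the noun it modified. The candidate pair is (profilin, actin), an
    annotated interaction. The sdp serializes to
    Protein1-nsubj-affects-dobj-properties-prep-of-Protein2 (7 tokens).
    """
    tokens = (
        Token(1, "Acanthamoeba", 2, "amod"),
        Token(2, "profilin", 3, "nsubj"),
        Token(3, "affects", 0, "root"),
        Token(4, "the", 6, "det"),
        Token(5, "mechanical", 6, "amod"),
        Token(6, "properties", 3, "dobj"),
        Token(7, "of", 6, "prep"),
        Token(8, "non-filamentous", 9, "amod"),
        Token(9, "actin", 6, "prep-of"),
    )
    parse = DependencyParse("fig2", tokens)
    instance = Instance("fig2-pair", "fig2", (2, 2), (9, 9), 1)
    return parse, instance
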