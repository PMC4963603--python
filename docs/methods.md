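# Methods

## Task and representation

The classifier decides, for one candidate pair of protein mentions in one
dependency-parsed sentence, whether the sentence asserts an interaction.
The input representation is the shortest dependency path (sdp) between
the two mentions, computed by breadth-first search over the undirected
head–dependent edge set. The two mentions are blinded to the reserved
symbols `Protein1`/`Protein2` so that the model cannot memorize protein
names, and the path is serialized as an interleaved word/relation
sequence (`Protein1 nsubj affects dobj properties prep-of Protein2`).
Relation labels are ordinary vocabulary items: they carry grammatical
signal (a `nsubj` edge into a verb marks its subject) and receive
embedding rows like any word.

Assumptions inherited from this representation:

* the parse is correct — parser errors propagate directly into the path;
* the interaction evidence lies on the path — interaction verbs elsewhere
  in the sentence are invisible to the model;
* one candidate pair is scored at a time; a sentence with several protein
  mentions contributes one instance per pair.

### Path-finding details

* The graph is undirected for path finding; edge direction is not encoded
  in the serialized sequence, which carries bare relation labels.
* BFS explores neighbors in ascending token index, so the returned path
  is deterministic when several shortest paths exist.
* Multi-token mentions are reduced to their syntactic head (the span
  token governed from outside the span); when zero or several such tokens
  exist the last span token is used and a warning logged.
* Interior path words are lowercased to match embedding-vocabulary
  conventions; the reserved symbols keep their case.
* Identical e1/e2 spans are rejected as degenerate rather than classified.
* Parses whose undirected edge set is disconnected are rejected at read
  time, which makes unreachable-endpoint errors impossible downstream.

### Fixed length

The network needs a fixed input length N (default 20). Shorter sequences
are padded with `PADDING`; longer ones are truncated by removing interior
tokens symmetrically around the path midpoint (`truncate="middle"`),
preserving both entity anchors and near-entity context. A `tail` strategy
(keep the first N−1 tokens plus `Protein2`) is available for comparison.

## Embeddings

The table maps every training-corpus token plus the three reserved
symbols to a row of **D** ∈ ℝ^(|V|×d) (d defaults to 300). Rows are
copied from a pretrained word2vec file when available, otherwise drawn
i.i.d. uniform from [−a, a]. With pretrained input, a is set to the
standard deviation of all pretrained entries so random rows match the
pretrained scale; a variance of unit-scale vectors would give a
degenerate near-zero range, so the spread interpretation is used. Without
pretrained input, a defaults to 0.25 (configurable).

* The `PADDING` row is identically zero and never receives gradient, so
  padding contributes no features.
* Every random row is drawn from its own seed derived from the master
  seed and the token string, making the table independent of vocabulary
  iteration order.
* Tokens first seen at predict time never enter the table; they are
  assigned a stable random vector whose seed derives from the token
  string, so repeated runs agree.
* Variants: `random` (frozen), `random_update` (rows of observed tokens
  fine-tuned), `pretrained` (frozen), `combined` (two channels: frozen
  pretrained + fine-tuned random, pooled features concatenated; each
  channel has its own filter bank).

## Network and training

Filters span h = 3 tokens by default (odd h keeps the key-word middle
token well defined; for even h the token left of center is used, with a
warning at attribution time). A feature is the Frobenius inner product of
filter and window plus bias, through tanh; the element-wise product
formulation only yields a scalar feature once summed over all h·d
entries, which is how the convolution is implemented. The feature map has
N−h+1 entries; max-over-time pooling takes the maximum (first index on
ties). The classifier MLP is O = f(W₂r + b₂), I = W₃O (no bias on the
confidence transform — deliberately), S = softmax(I) with
max-subtraction for numerical stability. C = 2 classes.

Training is per-example stochastic gradient descent with Adadelta
(ρ = 0.95, ε = 1e−6, Zeiler's published defaults), one update per
training pair, epoch order reshuffled per epoch from a derived seed.
Defaults: M = 100 filters, H = 500 hidden units, N = 20, d = 300,
100 epochs — scaled-down values are passed explicitly in tests and the
acceptance script (see below). Network weights initialize uniform
[−0.05, 0.05]. All arithmetic is float64; the analytic gradients are
validated against central finite differences (step 1e−5) to relative
error 1e−4 (observed ≈ 1e−11), including embedding-row gradients in the
trainable variants. The loss −log S[y] clamps S at 1e−12. No dropout or
L2 regularization is applied; the per-example updates plus the small
parameter count are the only regularizers, and the epoch-wise loss log is
returned so users can early-stop externally.

Determinism: one master seed fans out via SHA-256-derived per-stage seeds
(embedding init, weight init, shuffling, fold assignment, synthesis), so
any single stage can be varied while holding the others fixed, and two
runs with equal configuration are bit-identical.

## Key-word attribution

Each pooled feature identifies the window where its filter responded most
strongly; the middle token of that window is the filter's key-word for
the instance. Aggregating key-word counts over predicted-positive
instances ranks the tokens the model actually uses; on corpora with
planted interaction verbs the planted verb ranks first. `PADDING`
key-words (filters peaking in the padded suffix) are reported as-is
rather than hidden — they indicate filters acting as bias detectors.

## Evaluation

Precision, recall and F (harmonic mean 2PR/(P+R)) are computed from
confusion counts with the positive class = interaction. Zero-denominator
conventions: P = 0 when nothing is predicted positive, R = 0 with no gold
positives, F = 0 when P + R = 0.

Cross-validation is stratified at the instance level (folds preserve the
class ratio; sizes differ by at most one). Each fold's model is fit from
scratch, so vocabulary and random embedding rows are rebuilt from the
training folds only — held-out surface forms cannot leak into embedding
construction. Document-level fold grouping (by abstract) is a known
driver of score variance in PPI benchmarks; this package evaluates
instance-level folds, matching the common setting of sdp-based systems,
and the fold-assignment record emitted with every run makes any grouping
auditable. The learning-curve experiment draws one stratified split per
test fraction (0.1–0.9) and refits; multi-seed averaging is available via
`n_seeds`.

## Synthetic corpus

The generator emulates the single structural fact the method exploits:
the sdp between interacting proteins passes through an interaction verb.
Each sentence is a chain-shaped dependency tree rooted at a verb, with
the two single-token entities at the chain's ends and 0–4 distractor
tokens attached off-path; label-1 verbs come from a trigger lexicon,
label-0 verbs from a disjoint neutral lexicon. Serialized path lengths
are drawn from {5: 0.35, 7: 0.35, 9: 0.2, 11: 0.1} — short paths
dominate, as in real PPI corpora — and the class balance defaults to 1:1.
Raw length 3 is rejected: a two-node path has no interior verb to carry
the signal. Edge labels are drawn uniformly from
{nsubj, dobj, prep-of, amod, conj} for *all* path edges, and distractors
never contain lexicon verbs, so the on-path verb is the only token
systematically associated with the label: the label is conditionally
independent of everything else, and a classifier beating chance must be
reading path content. Attribution tests that ask "which planted trigger
was recovered" use a one-verb trigger lexicon so the expected key-word
is unambiguous.

What the generator does **not** emulate: lexical variety, negation and
speculation, parser noise, multi-pair sentences, the strongly
negative-heavy class balance of real PPI benchmarks, and the semantic
neighborhood structure of pretrained embeddings. Near-perfect synthetic
scores therefore certify implementation correctness — path extraction,
gradients, training dynamics, evaluation plumbing — not expected
performance on real biomedical corpora, which require external parsed
datasets and a multi-gigabyte pretrained embedding file and are out of
scope here.

## Problem sizes in tests and the acceptance script

Desk-scale settings are used throughout as the package's own choice of
test conditions: gradient checks on a tiny model (N = 5, d = 3, h = 3,
M = 2, H = 4) where finite differences are exact and cheap; capacity on
50 instances × 200 epochs; parameter recovery via 10-fold CV on 500
instances with d = 30, M = 20, H = 50, N = 15, 10 epochs; the learning
curve on 300 instances × 5 seeds. These sizes recover the planted signal
with large margin while keeping the full suite around a minute.

## Known limitations

* Purely CPU, per-example updates: training does not mini-batch or
  parallelize.
* The truncation strategy for over-length paths is a design choice
  (midpoint removal); no claim is made that it is optimal.
* `combined` duplicates the filter bank per channel rather than sharing
  it; sharing would halve parameters but couple the channels.
* The unseen-token policy (stable random vector) keeps prediction
  deterministic but gives out-of-vocabulary tokens no semantics; with
  pretrained embeddings, unseen words that exist in the pretrained file
  are still missed because the table is fixed at fit time.
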