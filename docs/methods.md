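# Methods

`cidrel` extracts document-level chemical-induced disease (CID) relations
from annotated biomedical abstracts. This note records the model, the
synthetic study design, the numerical choices, and the limitations that a
user of the results should know about.

## Task

A document is a title plus abstract with gold entity-mention annotations:
character spans typed as Chemical or Disease and normalized to MeSH
concept identifiers. Relations hold between *concepts*, not mentions, at
the document level. For a document with chemical concepts {c_i} and
disease concepts {d_j}, every ordered pair (c_i, d_j) is a candidate;
the model outputs p(r = 1 | c_i, d_j) and the task is binary
classification under a closed-world convention (unannotated pairs are
negatives). Evaluation is micro-averaged precision/recall/F1, reported
overall and split into *intra-sentence* pairs (some single sentence
mentions both concepts) and *inter-sentence* pairs (no sentence does).

## Model

1. **Encoding.** Tokens are embedded (`d_w`, default 300) and each
   sentence is contextualized by a bidirectional LSTM whose forward and
   backward outputs are *averaged*, keeping the contextual dimension at
   the one-side hidden size `d_h` (default 300). Three node kinds are
   built, each `[hidden ; type-embedding]` with a learned 50-dim type
   vector, so all nodes share dimension `d = d_h + d_t`:
   mention nodes (average of the hidden vectors over the mention's token
   span), entity nodes (average of their mentions' hidden parts — the
   type embedding is appended once, not nested, so a single convolution
   filter can serve all node kinds), and sentence nodes (average over the
   whole sentence).
2. **Document graph.** A binary symmetric adjacency over the
   N + R + T nodes with five edge rules: same-sentence mention pairs
   (MM), the complete sentence–sentence clique (SS, global context),
   mention–containing-sentence (MS), mention–concept (ME), and
   entity–sentence for every sentence holding one of the entity's
   mentions (ES). Self-loops are always present so a node's own state
   participates in its update. Degree normalization (none / symmetric /
   row) is exposed; the default is none, i.e. the convolution uses the
   raw adjacency.
3. **Aggregation.** Stacked graph convolutions
   `V_{l+1} = δ(A V_l W_l)` with LeakyReLU (slope 0.01) and per-layer
   filters. Four inter-layer connection mechanisms are implemented:
   plain, residual, dense (all layer outputs concatenated and projected
   back to `d` by a learned linear map, keeping the classifier
   dimension-agnostic), and the default *gated* update
   `g = σ(V_raw W_g + V_l U_g + b_g)`,
   `V_{l+1} = V_raw ⊙ g + V_l ⊙ (1 − g)` —
   an element-wise interpolation that lets every coordinate keep
   node-specific information across layers, counteracting the
   Laplacian-smoothing tendency of deep stacks. Default depth is 4.
4. **Classification.** For each candidate pair, a bilinear form over the
   final entity rows, `z_r = e_chemᵀ W_cls[r] e_dis` for r ∈ {0, 1}
   (the chemical is always the left argument), followed by a softmax; the
   loss is the summed negative log-likelihood of gold labels over all
   candidate pairs, optimized by SGD (momentum 0.9) with global-norm
   gradient clipping at 5, one document per step. The checkpoint with the
   best monitored F1 (dev set when available, else training set) is kept;
   training stops early after `patience` non-improving epochs or when the
   monitored F1 reaches `stop_f1` (default 1.0).

All numerics run in double precision on a small in-package reverse-mode
automatic-differentiation engine over numpy arrays; analytic gradients
are validated against central finite differences in the acceptance suite.

### Over-smoothing diagnostic

`oversmoothing_metric` is the mean pairwise cosine similarity of node
rows (1 ⇔ all rows parallel). In the linear limit — row-normalized
adjacency, identity filter, identity activation — the plain update is a
neighborhood-averaging (Laplacian smoothing) step, and on a connected
graph the metric provably converges to 1 with depth; the package
demonstrates ≥ 0.999 by depth 64 on a random 10-node graph, while a gate
biased to −10 (g ≈ 4.5·10⁻⁵) keeps the metric within 10⁻³ of its initial
value at the same depth. This isolates the mechanism the gate exists for.

## PubTator input conventions

Offsets are 0-based half-open into `title + separator + abstract`
(separator configurable, default `"\n"`), validated against every
annotated surface string. Composite concept annotations (`D…|D…`) expand
to one mention per identifier sharing the span; unnormalized (`-1`)
annotations are dropped with a warning — concepts are the classification
unit, so a span without an identifier cannot participate. The title is
treated as the first sentence. Sentence splitting is a Punkt-style
heuristic (abbreviation list, single-initial and lowercase-continuation
guards) and word tokenization a Treebank-style regex; both are pluggable
and recorded in the reader configuration. A proposed sentence boundary
falling inside a mention is suppressed, so every mention lies in exactly
one sentence. Embedding lookup lowercases with original-case fallback;
out-of-vocabulary tokens map to a single learned `<unk>` vector.
Pretrained vectors in the word2vec text dialect (optionally gzipped) can
seed the table.

## Synthetic study design

Real CID corpora cannot be redistributed with the package, so all
quantitative studies run on generated corpora that reproduce the
*structural* statistics of such corpora — multi-sentence abstracts,
MeSH-shaped concept ids drawn from a shared pool, ~2/3 of concepts with
mentions in more than one sentence, an exact fraction
(`inter_fraction`, default 0.30) of positive pairs realized only across
sentences — while keeping the pair label a deterministic function of
lexical witness templates (cue token `induced`):

* **Intra-sentence positives**: `Chm… induced Dis… .` in one sentence.
* **Inter-sentence positives** live in *anaphoric documents* with one
  chemical and one disease: an `… was administered .` sentence, a plain
  disease sentence, and a repeated mention-less verdict
  `The drug induced … .` A fraction `decoy_rate` (default 0.2) of all
  documents are structurally identical decoys whose verdict block is
  plain filler and whose pair is negative.
* **Negatives** co-occur in plain sentences without the cue.

Design rationale. Any lexical cue inside a sentence containing an
entity's mention is visible to the sequence encoder alone, so a
generator built only from such cues cannot distinguish a model that
aggregates document context from one that does not — we verified
empirically that an encoder-only classifier solves such corpora
perfectly. The mention-less verdict sentence is the minimal construction
whose information *provably* cannot reach encoder-only entity
representations (which depend only on the sentences containing the
entities' mentions) yet reaches every entity through two hops of graph
propagation via the sentence clique. Matched decoys remove the shortcut
"anaphoric document shape ⇒ positive". The verdict block is repeated
(`verdict_repeats`, default 3), as abstracts restate conclusions, which
keeps the propagated signal at a learnable magnitude. All positives in a
document share one hub chemical, because two disjoint positive pairs
would make their cross pairs carry both witness cues while being labeled
negative — the label would stop being a function of the visible cues.

Structure and lexicon come from two independent seeded RNG streams, so
structural counts are stable under vocabulary changes; identical seeds
give byte-identical PubTator output. The exact inter-sentence count
(round-half-up of `inter_fraction ×` positives) is realized by a greedy
document-conversion procedure with a fixed-point guard; train/dev/test
splits are slices of one generation run and therefore share the concept
pool and lexicon, so held-out evaluation measures generalization over
contexts rather than vocabulary mismatch.

What the generator does **not** emulate: real biomedical language,
hypernymy and coordination in mentions, annotation noise, the heavy and
variable label imbalance of real corpora, or discourse structure beyond
the anaphoric template. Passing the synthetic studies therefore shows
that the implementation is correct and that the architecture can exploit
document-level structure — not that it attains any particular score on
real corpora.

## Reference experiment protocols

Defined once in `cidrel.experiments` and used by both the tests and
`scripts/acceptance.py`. Synthetic-study models are small
(`d_w = d_h = 24`, `d_t = 8`) — the planted signals are low-dimensional
and this keeps every protocol affordable on one CPU; optimization uses
lr 0.02 (momentum 0.9, clip 5, ≤ 60 epochs, patience 12, dev-monitored).
During development, higher learning rates (0.05–0.1) fit the training
set but reliably failed to pick up the propagated verdict feature; 0.02
learns it consistently.

* **End-to-end recovery** — 200 train / 30 dev / 50 test documents,
  default generator; median over 3 training seeds of training and
  held-out F1.
* **Aggregation ablation** — a contrast corpus (inter_fraction 0.5,
  decoy_rate 0.35, 200 train / 40 dev / 40 test): the full 4-layer gated
  model versus the classifier applied directly to encoder-only entity
  nodes. The decoy-heavy corpus makes the anaphoric shape weakly
  predictive, so the inter-sentence block cleanly separates models that
  do and do not aggregate; intra-sentence F1 stays ≈ 1 for both.
* **Depth comparison** — gated vs. plain stacks at depth 8 (120 train /
  30 dev, lr 0.02, ≤ 80 epochs, patience 20), median dev F1 over 3
  seeds; deep plain stacks smooth node representations into
  indistinguishability while the gated stack keeps learning.

## Numerical choices

* Double precision throughout; softmax and the loss are log-sum-exp
  stabilized (no raw `log 0`).
* Initialization: symmetric uniform scaled by 1/√fan-in for weight
  matrices; gate biases 0 (balanced gate ≈ 0.5); LSTM forget-gate bias 1
  (standard memory-friendly start); embeddings uniform in ±0.1; all
  draws from a seeded generator, so runs are reproducible bit-for-bit up
  to floating-point associativity.
* Degenerate inputs: empty corpora and all-negative corpora are legal
  (F1 reported as 0 under the 0/0 → 0 convention); documents lacking a
  chemical or a disease contribute no candidate pairs; empty sentences
  are rejected upstream.
* Gradient checking uses step 3·10⁻⁵ (balancing LeakyReLU-kink
  truncation against round-off) and a 10⁻³ absolute floor in the
  relative-error denominator so vanishing recurrent gradients are
  compared absolutely rather than as ratios of floating-point noise.
* Divergence (non-finite loss) aborts training with a diagnostic; the
  ablation harness records such a cell as a zero-score report instead of
  crashing the sweep.

## Limitations

* The bilinear pair scorer over averaged, propagated representations
  learns *feature-presence* rules well but systematic *identity-binding*
  rules (e.g. matching an arbitrary shared token across two sentences)
  poorly at this scale; the synthetic design deliberately avoids making
  the label depend on such binding.
* The sentence clique makes all sentences two hops from everything;
  document-global evidence is therefore attributed to pairs only through
  the entity-side markers, which mirrors how the architecture behaves on
  real data (inter-sentence scores well below intra-sentence ones).
* Tokenization heuristics are tuned for abstract-like text; no character
  level fallback exists for languages or formats with different
  conventions.
* Training is CPU-bound pure numpy; corpora in the thousands of
  documents at the reference dimensions train in minutes, but the
  full-size configuration (300/300/50) on real corpora is outside the
  intended scope of this implementation.
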