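# cidrel

Document-level **chemical-induced disease (CID) relation extraction** with
a gated graph convolutional network over a heterogeneous document graph.

Curated chemical–disease associations (as in the Comparative
Toxicogenomics Database) lag far behind the literature; automatic
extraction from PubMed abstracts has to decide, for every pair of
normalized concepts in a document, whether the text asserts that the
chemical induces the disease. The hard part is that an entity is usually
mentioned several times across sentences and a substantial share of true
relations (about 30% in the BioCreative V CDR benchmark) is never stated
inside a single sentence — the evidence must be aggregated across the
document. `cidrel` is a self-contained, CPU-friendly implementation of a
graph-based extractor for this task, aimed at researchers who want an
inspectable reference implementation with a fully testable synthetic
benchmark rather than a GPU-scale production system.

## Model

For a document with sentences s_1…s_T, mentions m_1…m_N and normalized
concepts c_1…c_R:

1. **BiLSTM encoding.** Each sentence is encoded token-wise by a
   bidirectional LSTM; forward and backward states are averaged, giving
   contextual vectors h_t ∈ ℝ^{d_h}.
2. **Node construction.** Mention nodes average the h_t over the
   mention's span; entity nodes average their mentions; sentence nodes
   average the whole sentence. Each node appends a learned node-type
   embedding (dim d_t), so every node lives in ℝ^{d}, d = d_h + d_t.
3. **Heterogeneous document graph.** A binary symmetric adjacency
   A ∈ ℝ^{(N+R+T)×(N+R+T)} with self-loops connects: same-sentence
   mention pairs, every sentence pair (a clique carrying global context),
   mentions to their sentence, mentions to their concept, and entities to
   every sentence containing one of their mentions.
4. **Gated graph convolutions.** L layers (default 4) of
   V_raw = LeakyReLU(A V_l W_l), combined through a sigmoid gate
   g = σ(V_raw W_g + V_l U_g + b_g), V_{l+1} = V_raw⊙g + V_l⊙(1−g).
   The gate counteracts *over-smoothing* — the tendency of stacked
   convolutions (a form of Laplacian smoothing) to make all node
   representations indistinguishable. Plain, residual and dense-concat
   connection modes are also implemented for comparison.
5. **Bilinear classifier.** For every chemical×disease concept pair,
   logits z_r = e_chemᵀ W_cls[r] e_dis (r ∈ {0,1}) and a softmax;
   training minimizes the negative log-likelihood of the gold labels over
   all candidate pairs with SGD.

Everything runs on a small reverse-mode autodiff engine over numpy —
no deep-learning framework required — and is exact to double precision
(gradients are verified against finite differences in the test suite).

## Worked example

Corpora are read and written in **PubTator** format (the format of the
BioCreative V CDR corpus). Since that corpus cannot be bundled, the
package ships a generator of PubTator-valid synthetic corpora whose
relation labels are a deterministic function of lexical witness
templates, with an exact, configurable fraction of inter-sentence
positives (see `docs/methods.md` for the design):

```bash
python examples/03_train_and_evaluate.py
```

trains a small 4-layer gated model on 80 generated documents and prints

```
trained for 34 epochs (final loss 0.00)
overall  P=1.000 R=1.000 F1=1.000 (tp=38 fp=0 fn=0)
intra    P=1.000 R=1.000 F1=1.000 (tp=27 fp=0 fn=0)
inter    P=1.000 R=1.000 F1=1.000 (tp=11 fp=0 fn=0)
```

— all 38 held-out gold pairs recovered, including the 11 whose evidence
never co-occurs in one sentence (`intra`/`inter` is decided by sentence
co-occurrence of the two concepts' mentions). The over-smoothing
mechanism itself can be seen in isolation with
`python examples/04_oversmoothing_demo.py`:

```
depth   plain    gated
    1  0.6204  0.0043
    8  0.9998  0.0043
   64  1.0000  0.0048
```

where the number is the mean pairwise cosine similarity of the node
representations: plain convolutions collapse a random 10-node graph onto
one ray within a few layers, while a nearly closed gate preserves the
initial geometry (0.0043) to depth 64.

The same functionality is available as a CLI:

```bash
cidrel synth --n-train 200 --n-dev 30 --n-test 50 --seed 1 --out-dir data/
cidrel train --train data/train.pubtator --dev data/dev.pubtator \
             --d-w 24 --d-h 24 --d-t 8 --lr 0.02 --out-dir run/
cidrel predict --model run/model.npz --input data/test.pubtator --out preds.tsv
cidrel evaluate --gold data/test.pubtator --pred preds.tsv
cidrel ablate --train data/train.pubtator --test data/test.pubtator
cidrel diagnose-smoothing --layers 64 --mode plain
```

Every run writes its resolved configuration next to its outputs.

## Layout

```
src/cidrel/
  types.py        document / mention / concept / relation model
  corpus_io.py    PubTator I/O, sentence splitting, mention alignment
  synthetic.py    synthetic-corpus generator and corpus statistics
  _autodiff.py    reverse-mode autodiff on numpy
  encoder.py      embeddings, BiLSTM, node construction
  graph.py        document-graph construction and normalization
  gcn.py          convolution layers, gating, over-smoothing diagnostics
  model.py        full model, forward pass, (de)serialization
  train.py        loss, SGD loop, prediction
  evaluate.py     P/R/F1 with intra/inter split, ablation harness
  experiments.py  reference synthetic-study protocols
  cli.py          command-line interface
```
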