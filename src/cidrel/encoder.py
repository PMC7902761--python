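"""Sentence encoding and node construction.

Each sentence is encoded token-by-token with a bidirectional LSTM; the
forward and backward hidden states are *averaged* (not concatenated), so
the contextual dimension stays ``d_h``. Three kinds of graph nodes are then
built, each carrying a learned node-type embedding appended to its hidden
part (total node dimension ``d = d_h + d_t``):

* mention node — average of the hidden vectors over the mention's tokens;
* entity node  — average of its mentions' hidden parts (the type embedding
  is appended once, keeping the dimension uniform across node kinds, as
  required by the shared convolution filter);
* sentence node — average of the hidden vectors over the whole sentence.

All functions here run both on plain numpy arrays (for closed-form test
oracles) and on autodiff tensors (for training); see :mod:`cidrel._autodiff`.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autodiff as F
from ._autodiff import Tensor, value
from .types import Document


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

UNK = "<unk>"


class EmbeddingTable:
    """Token → row lookup over a dense embedding matrix.

    Lookup lowercases the token first and falls back to the original case;
    anything else maps to a single learned ``<unk>`` vector (row 0).
    """

    def __init__(self, vocab: dict[str, int], matrix, d_w: int):
        if UNK not in vocab:
            raise ValueError("embedding table must contain the <unk> token")
        self.vocab = vocab
        self.matrix = matrix  # (|vocab|, d_w), Tensor or ndarray
        self.d_w = d_w

    def index(self, token: str) -> int:
        v = self.vocab
        low = token.lower()
        if low in v:
            return v[low]
        if token in v:
            return v[token]
        return v[UNK]

    def indices(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.intp)

    def lookup(self, tokens: Sequence[str]):
        return F.gather_rows(self.matrix, self.indices(tokens))

    @property
    def trainable(self) -> bool:
        return isinstance(self.matrix, Tensor) and self.matrix.requires_grad

    @classmethod
    def build(
        cls,
        tokens: Sequence[str],
        d_w: int,
        rng: np.random.Generator,
        trainable: bool = True,
        pretrained: dict[str, np.ndarray] | None = None,
        scale: float = 0.1,
    ) -> "EmbeddingTable":
        """Create a table over the lowercased vocabulary of ``tokens``.

        Rows are drawn uniform in ``[-scale, scale]``; rows for tokens
        present in ``pretrained`` are copied from it instead.
        """
        vocab = {UNK: 0}
        for t in tokens:
            low = t.lower()
            if low not in vocab:
                vocab[low] = len(vocab)
        mat = rng.uniform(-scale, scale, size=(len(vocab), d_w))
        if pretrained:
            for tok, row in vocab.items():
                if tok in pretrained:
                    mat[row] = pretrained[tok][:d_w]
        return cls(vocab, Tensor(mat, requires_grad=trainable), d_w)


def load_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read pretrained vectors in the whitespace word2vec text dialect
    (``token v1 … vD`` per line, optional ``count dim`` header); ``.gz``
    files are decompressed transparently."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    vectors: dict[str, np.ndarray] = {}
    with opener(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) == 2 and all(p.lstrip("-").isdigit() for p in first):
            pass  # header line
        elif first:
            vectors[first[0]] = np.array([float(x) for x in first[1:]])
        for line in fh:
            parts = line.rstrip().split(" ")
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return vectors


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

@dataclass
class LstmParams:
    """One direction of an LSTM: input maps W_*, recurrent maps U_*, biases
    b_* for the input/forget/output gates and the candidate cell update."""

    W_i: object; U_i: object; b_i: object
    W_f: object; U_f: object; b_f: object
    W_o: object; U_o: object; b_o: object
    W_c: object; U_c: object; b_c: object
    d_w: int = 300
    d_h: int = 300

    @classmethod
    def init(cls, d_w: int, d_h: int, rng: np.random.Generator,
             forget_bias: float = 1.0) -> "LstmParams":
        def w():
            return F.parameter(rng, (d_w, d_h), fan_in=d_w)

        def u():
            return F.parameter(rng, (d_h, d_h), fan_in=d_h)

        def b(v=0.0):
            return Tensor(np.full(d_h, v), requires_grad=True)

        return cls(
            W_i=w(), U_i=u(), b_i=b(),
            W_f=w(), U_f=u(), b_f=b(forget_bias),
            W_o=w(), U_o=u(), b_o=b(),
            W_c=w(), U_c=u(), b_c=b(),
            d_w=d_w, d_h=d_h,
        )

    def parameters(self) -> list[Tensor]:
        return [getattr(self, n) for n in
                ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f",
                 "W_o", "U_o", "b_o", "W_c", "U_c", "b_c")]


def lstm_step(x_t, h_prev, c_prev, params: LstmParams):
    """One LSTM cell update; ``x_t`` may be a single vector or a batch.

    i, f, o are sigmoid gates in (0,1); the candidate cell state is a tanh;
    ``c_t = i ⊙ c̃ + f ⊙ c_{t-1}`` and ``h_t = o ⊙ tanh(c_t)``.
    """
    i = F.sigmoid(F.matmul(x_t, params.W_i) + F.matmul(h_prev, params.U_i) + params.b_i)
    f = F.sigmoid(F.matmul(x_t, params.W_f) + F.matmul(h_prev, params.U_f) + params.b_f)
    o = F.sigmoid(F.matmul(x_t, params.W_o) + F.matmul(h_prev, params.U_o) + params.b_o)
    c_tilde = F.tanh(F.matmul(x_t, params.W_c) + F.matmul(h_prev, params.U_c) + params.b_c)
    c_t = i * c_tilde + f * c_prev
    h_t = o * F.tanh(c_t)
    return h_t, c_t


def lstm_run(X, params: LstmParams):
    """Unidirectional pass over a (n, d_w) sequence; returns (n, d_h)."""
    n = value(X).shape[0]
    h = np.zeros(params.d_h)
    c = np.zeros(params.d_h)
    outs = []
    for t in range(n):
        x_t = F.gather_rows(X, [t])
        h, c = lstm_step(x_t, h, c, params)
        outs.append(h)
    return F.concat(outs, axis=0)


def bilstm_encode(sentence_tokens: Sequence[str], embeddings: EmbeddingTable,
                  params_fwd: LstmParams, params_bwd: LstmParams):
    """Contextualize one sentence: the backward LSTM runs on the reversed
    token sequence, its outputs are re-reversed, and the two directions are
    averaged — output is (n, d_h)."""
    if len(sentence_tokens) == 0:
        raise ValueError("cannot encode an empty sentence")
    X = embeddings.lookup(sentence_tokens)
    H_f = lstm_run(X, params_fwd)
    Xr = F.gather_rows(X, list(range(len(sentence_tokens) - 1, -1, -1)))
    H_b_rev = lstm_run(Xr, params_bwd)
    H_b = F.gather_rows(H_b_rev, list(range(len(sentence_tokens) - 1, -1, -1)))
    return 0.5 * (H_f + H_b)


def bilstm_encode_batch(index_lists: Sequence[np.ndarray], matrix,
                        params_fwd: LstmParams, params_bwd: LstmParams):
    """Encode several sentences at once with length masking.

    ``index_lists`` holds the embedding-row indices of each sentence.
    Returns ``(H_all, offsets)`` where ``H_all`` stacks the token vectors of
    all sentences in order and ``offsets[i]`` is the row of sentence i's
    first token. Numerically identical to per-sentence :func:`bilstm_encode`.
    """
    S = len(index_lists)
    lengths = np.array([len(ix) for ix in index_lists])
    if np.any(lengths == 0):
        raise ValueError("cannot encode an empty sentence")
    L = int(lengths.max())
    pad_f = np.zeros((S, L), dtype=np.intp)
    pad_b = np.zeros((S, L), dtype=np.intp)
    for s, ix in enumerate(index_lists):
        pad_f[s, : len(ix)] = ix
        pad_b[s, : len(ix)] = ix[::-1]

    def run(pad, params):
        h = np.zeros((S, params.d_h))
        c = np.zeros((S, params.d_h))
        steps = []
        for t in range(L):
            x_t = F.gather_rows(matrix, pad[:, t])
            mask = (t < lengths).astype(float)[:, None]
            h_new, c_new = lstm_step(x_t, h, c, params)
            h = mask * h_new + (1.0 - mask) * h
            c = mask * c_new + (1.0 - mask) * c
            steps.append(h)
        return F.concat(steps, axis=0)  # (L*S, d_h), row t*S + s

    big_f = run(pad_f, params_fwd)
    big_b = run(pad_b, params_bwd)

    idx_f, idx_b = [], []
    for s, n in enumerate(lengths):
        for j in range(n):
            idx_f.append(j * S + s)
            idx_b.append((n - 1 - j) * S + s)
    H_all = 0.5 * (F.gather_rows(big_f, idx_f) + F.gather_rows(big_b, idx_b))
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return H_all, offsets


# ---------------------------------------------------------------------------
# Node construction
# ---------------------------------------------------------------------------

@dataclass
class NodeTypeEmbeddings:
    """Learned type vectors (dim d_t) appended to mention/entity/sentence
    node representations."""

    t_m: object
    t_e: object
    t_s: object
    d_t: int = 50

    @classmethod
    def init(cls, d_t: int, rng: np.random.Generator) -> "NodeTypeEmbeddings":
        return cls(
            t_m=Tensor(rng.uniform(-0.1, 0.1, size=d_t), requires_grad=True),
            t_e=Tensor(rng.uniform(-0.1, 0.1, size=d_t), requires_grad=True),
            t_s=Tensor(rng.uniform(-0.1, 0.1, size=d_t), requires_grad=True),
            d_t=d_t,
        )

    def parameters(self) -> list[Tensor]:
        return [self.t_m, self.t_e, self.t_s]


@dataclass
class NodeSet:
    """Ordered node representations of one document: N mention rows, then
    R entity rows, then T sentence rows; ``V`` is (N+R+T, d_h + d_t)."""

    V: object
    kinds: list[str]
    mention_rows: dict[int, int]
    entity_rows: dict[str, int]
    sentence_rows: dict[int, int]

    @property
    def n_nodes(self) -> int:
        return value(self.V).shape[0]


def node_layout(doc: Document):
    """Row indices for the node ordering mentions → entities → sentences."""
    N, R, T = len(doc.mentions), len(doc.concepts), doc.n_sentences
    mention_rows = {i: i for i in range(N)}
    entity_rows = {c.concept_id: N + j for j, c in enumerate(doc.concepts)}
    sentence_rows = {i: N + R + i for i in range(T)}
    kinds = ["mention"] * N + ["entity"] * R + ["sentence"] * T
    return kinds, mention_rows, entity_rows, sentence_rows


def _averaging_matrices(doc: Document, offsets: np.ndarray, total_tokens: int):
    N, R, T = len(doc.mentions), len(doc.concepts), doc.n_sentences
    M_m = np.zeros((N, total_tokens))
    for j, m in enumerate(doc.mentions):
        a, b = m.token_span
        lo = offsets[m.sentence_index] + a
        M_m[j, lo : lo + (b - a)] = 1.0 / (b - a)
    E_map = np.zeros((R, N))
    for r, c in enumerate(doc.concepts):
        E_map[r, c.mention_indices] = 1.0 / len(c.mention_indices)
    M_s = np.zeros((T, total_tokens))
    for i, toks in enumerate(doc.sentences):
        M_s[i, offsets[i] : offsets[i] + len(toks)] = 1.0 / len(toks)
    return M_m, E_map, M_s


def build_nodes_flat(doc: Document, H_all, offsets: np.ndarray,
                     type_embeddings: NodeTypeEmbeddings) -> NodeSet:
    """Build the node matrix from the concatenated token representations of
    all sentences (``H_all`` row ``offsets[i] + j`` = sentence i, token j)."""
    total = value(H_all).shape[0]
    M_m, E_map, M_s = _averaging_matrices(doc, offsets, total)
    mention_h = F.matmul(M_m, H_all)
    entity_h = F.matmul(E_map, mention_h)
    sentence_h = F.matmul(M_s, H_all)
    hidden = F.concat([mention_h, entity_h, sentence_h], axis=0)

    kinds, mention_rows, entity_rows, sentence_rows = node_layout(doc)
    kind_idx = np.array([{"mention": 0, "entity": 1, "sentence": 2}[k] for k in kinds])
    type_part = F.gather_rows(
        F.stack([type_embeddings.t_m, type_embeddings.t_e, type_embeddings.t_s]),
        kind_idx,
    )
    V = F.concat([hidden, type_part], axis=1)
    return NodeSet(V, kinds, mention_rows, entity_rows, sentence_rows)


def build_nodes(doc: Document, H_per_sentence: Sequence,
                type_embeddings: NodeTypeEmbeddings) -> NodeSet:
    """Node construction from per-sentence contextual matrices (n_i, d_h)."""
    if len(H_per_sentence) != doc.n_sentences:
        raise ValueError("one H matrix per sentence is required")
    for c in doc.concepts:
        if not c.mention_indices:
            raise ValueError(f"concept {c.concept_id} has no mentions")
    lengths = [value(H).shape[0] for H in H_per_sentence]
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    H_all = F.concat(list(H_per_sentence), axis=0)
    return build_nodes_flat(doc, H_all, offsets, type_embeddings)
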