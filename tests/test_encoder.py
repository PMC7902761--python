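"""BiLSTM encoding and node construction against hand/brute-force oracles."""
from __future__ import annotations

import gzip
import math

import numpy as np
import pytest

import cidrel as cr
from cidrel import _autodiff as F
from cidrel.encoder import (
    EmbeddingTable,
    LstmParams,
    NodeTypeEmbeddings,
    bilstm_encode,
    bilstm_encode_batch,
    build_nodes,
    load_word2vec_text,
    lstm_run,
    lstm_step,
)
from cidrel.types import Document, EntityConcept, EntityType, Mention


def zero_params(d_w, d_h):
    z = lambda *s: np.zeros(s)
    return LstmParams(
        W_i=z(d_w, d_h), U_i=z(d_h, d_h), b_i=z(d_h),
        W_f=z(d_w, d_h), U_f=z(d_h, d_h), b_f=z(d_h),
        W_o=z(d_w, d_h), U_o=z(d_h, d_h), b_o=z(d_h),
        W_c=z(d_w, d_h), U_c=z(d_h, d_h), b_c=z(d_h),
        d_w=d_w, d_h=d_h,
    )


def ones_params(d_w, d_h):
    p = zero_params(d_w, d_h)
    for n in ("W_i", "U_i", "W_f", "U_f", "W_o", "U_o", "W_c", "U_c"):
        setattr(p, n, np.ones(getattr(p, n).shape))
    return p


def sigma(x):
    return 1.0 / (1.0 + math.exp(-x))


def test_lstm_step_zero_parameters_give_zero_state():
    p = zero_params(3, 4)
    h, c = np.zeros(4), np.zeros(4)
    for x in np.random.default_rng(0).normal(size=(5, 3)):
        h, c = lstm_step(x, h, c, p)
        assert np.allclose(c, 0) and np.allclose(h, 0)


def test_lstm_step_scalar_hand_arithmetic():
    # d_w = d_h = 1, x = 1, all weights 1, biases 0, zero initial state
    p = ones_params(1, 1)
    h, c = lstm_step(np.array([1.0]), np.zeros(1), np.zeros(1), p)
    i = f = o = sigma(1.0)
    c_tilde = math.tanh(1.0)
    c_exp = i * c_tilde
    h_exp = o * math.tanh(c_exp)
    assert abs(float(np.ravel(c)[0]) - c_exp) < 1e-10
    assert abs(float(np.ravel(h)[0]) - h_exp) < 1e-10


def test_lstm_gates_bounded_and_state_bounded():
    rng = np.random.default_rng(1)
    p = zero_params(4, 4)
    for n in ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f", "W_o", "U_o", "b_o",
              "W_c", "U_c", "b_c"):
        setattr(p, n, rng.normal(size=getattr(p, n).shape) * 2)
    h, c = np.zeros(4), np.zeros(4)
    for x in rng.normal(size=(10, 4)):
        # recompute gates explicitly: sigmoids are strictly inside (0,1)
        for W, U, b in ((p.W_i, p.U_i, p.b_i), (p.W_f, p.U_f, p.b_f),
                        (p.W_o, p.U_o, p.b_o)):
            g = F.sigmoid(x @ W + h @ U + b)
            assert np.all(g > 0) and np.all(g < 1)
        h, c = lstm_step(x, h, c, p)
        assert np.all(np.abs(h) < 1)  # |o| < 1 and |tanh(c)| < 1


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(0)
    vocab = {"<unk>": 0, "aba": 1, "cdc": 2, "efe": 3}
    return EmbeddingTable(vocab, rng.normal(size=(4, 2)), 2)


def test_bilstm_zero_params_zero_output(toy_table):
    p = zero_params(2, 3)
    H = bilstm_encode(["aba", "cdc"], toy_table, p, p)
    assert np.allclose(F.value(H), 0)


def test_bilstm_palindrome_symmetry(toy_table):
    rng = np.random.default_rng(3)
    p = zero_params(2, 3)
    for n in ("W_i", "U_i", "W_f", "U_f", "W_o", "U_o", "W_c", "U_c"):
        setattr(p, n, rng.normal(size=getattr(p, n).shape))
    H = F.value(bilstm_encode(["aba", "cdc", "aba"], toy_table, p, p))
    assert np.allclose(H, H[::-1], atol=1e-12)


def test_bilstm_scalar_unrolled_oracle():
    """n=3, d_w=d_h=1: compare against an explicitly unrolled recurrence."""
    table = EmbeddingTable({"<unk>": 0, "a": 1, "b": 2, "c": 3},
                           np.array([[0.0], [0.3], [-0.5], [0.9]]), 1)
    rng = np.random.default_rng(5)
    pf, pb = zero_params(1, 1), zero_params(1, 1)
    for p in (pf, pb):
        for n in ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f", "W_o", "U_o",
                  "b_o", "W_c", "U_c", "b_c"):
            setattr(p, n, rng.normal(size=getattr(p, n).shape))

    def unroll(xs, p):
        h = c = 0.0
        out = []
        for x in xs:
            i = sigma(x * p.W_i[0, 0] + h * p.U_i[0, 0] + p.b_i[0])
            f = sigma(x * p.W_f[0, 0] + h * p.U_f[0, 0] + p.b_f[0])
            o = sigma(x * p.W_o[0, 0] + h * p.U_o[0, 0] + p.b_o[0])
            ct = math.tanh(x * p.W_c[0, 0] + h * p.U_c[0, 0] + p.b_c[0])
            c = i * ct + f * c
            h = o * math.tanh(c)
            out.append(h)
        return out

    xs = [0.3, -0.5, 0.9]
    fwd = unroll(xs, pf)
    bwd = unroll(xs[::-1], pb)[::-1]
    expected = [(a + b) / 2 for a, b in zip(fwd, bwd)]
    H = F.value(bilstm_encode(["a", "b", "c"], table, pf, pb))
    assert np.allclose(H[:, 0], expected, atol=1e-10)


def test_batched_encoding_matches_per_sentence(small_corpus):
    doc = small_corpus.documents[0]
    rng = np.random.default_rng(8)
    tokens = [t for s in doc.sentences for t in s]
    table = EmbeddingTable.build(tokens, 5, rng)
    pf = LstmParams.init(5, 4, rng)
    pb = LstmParams.init(5, 4, rng)
    H_all, offsets = bilstm_encode_batch(
        [table.indices(s) for s in doc.sentences], table.matrix, pf, pb
    )
    H_all = F.value(H_all)
    for i, sent in enumerate(doc.sentences):
        H_one = F.value(bilstm_encode(sent, table, pf, pb))
        got = H_all[offsets[i] : offsets[i] + len(sent)]
        assert np.allclose(got, H_one, atol=1e-12)


def _nodes_fixture_doc():
    sents = [["Aaa", "bb", "cc"], ["Ddd", "ee"]]
    mentions = [
        Mention("d", 0, 3, "Aaa", EntityType.CHEMICAL, "C1",
                sentence_index=0, token_span=(0, 1)),
        Mention("d", 4, 6, "bb", EntityType.CHEMICAL, "C1",
                sentence_index=0, token_span=(1, 2)),
        Mention("d", 10, 13, "Ddd", EntityType.DISEASE, "D1",
                sentence_index=1, token_span=(0, 1)),
    ]
    concepts = [EntityConcept("C1", EntityType.CHEMICAL, [0, 1]),
                EntityConcept("D1", EntityType.DISEASE, [2])]
    return Document("d", "Aaa bb cc", "Ddd ee", sentences=sents,
                    mentions=mentions, concepts=concepts)


def test_build_nodes_hand_averages():
    doc = _nodes_fixture_doc()
    H0 = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    H1 = np.array([[10.0, 20.0], [30.0, 40.0]])
    types = NodeTypeEmbeddings(
        t_m=np.array([0.1]), t_e=np.array([0.2]), t_s=np.array([0.3]), d_t=1
    )
    nodes = build_nodes(doc, [H0, H1], types)
    V = F.value(nodes.V)
    assert V.shape == (3 + 2 + 2, 3)  # N + R + T rows, d_h + d_t columns
    # mention nodes: averages over token spans (single tokens here)
    assert np.allclose(V[0], [1, 2, 0.1])
    assert np.allclose(V[1], [3, 4, 0.1])
    assert np.allclose(V[2], [10, 20, 0.1])
    # entity nodes: averages of mention hidden parts, one type embedding
    assert np.allclose(V[3], [2, 3, 0.2])  # mean of (1,2) and (3,4)
    assert np.allclose(V[4], [10, 20, 0.2])
    # sentence nodes: averages over all tokens
    assert np.allclose(V[5], [3, 4, 0.3])
    assert np.allclose(V[6], [20, 30, 0.3])
    assert nodes.entity_rows == {"C1": 3, "D1": 4}


def test_entity_with_identical_mentions_is_idempotent():
    doc = _nodes_fixture_doc()
    H0 = np.array([[7.0, -1.0], [7.0, -1.0], [0.0, 0.0]])
    H1 = np.zeros((2, 2))
    types = NodeTypeEmbeddings(t_m=np.zeros(1), t_e=np.zeros(1),
                               t_s=np.zeros(1), d_t=1)
    V = F.value(build_nodes(doc, [H0, H1], types).V)
    assert np.allclose(V[3][:2], [7.0, -1.0])


def test_entity_average_is_mention_order_invariant():
    doc = _nodes_fixture_doc()
    H0 = np.array([[1.0, 0.0], [0.0, 2.0], [5.0, 5.0]])
    H1 = np.ones((2, 2))
    types = NodeTypeEmbeddings(t_m=np.zeros(1), t_e=np.zeros(1),
                               t_s=np.zeros(1), d_t=1)
    V1 = F.value(build_nodes(doc, [H0, H1], types).V)
    doc.concepts[0].mention_indices = [1, 0]
    V2 = F.value(build_nodes(doc, [H0, H1], types).V)
    assert np.allclose(V1, V2)


def test_empty_sentence_and_missing_mention_errors(toy_table):
    p = zero_params(2, 3)
    with pytest.raises(ValueError):
        bilstm_encode([], toy_table, p, p)
    doc = _nodes_fixture_doc()
    doc.concepts[0].mention_indices = [0, 1]
    with pytest.raises(ValueError):
        build_nodes(doc, [np.zeros((3, 2))], None)  # wrong sentence count


def test_embedding_lookup_case_and_oov(toy_table):
    assert toy_table.index("ABA") == 1  # lowercase first
    assert toy_table.index("aba") == 1
    assert toy_table.index("zzz") == 0  # UNK
    vocab = {"<unk>": 0, "usa": 1, "USA": 2}
    t = EmbeddingTable(vocab, np.eye(3), 3)
    assert t.index("usa") == 1
    assert t.index("USA") == 1  # lowercase hit wins
    assert t.index("Usa") == 1


def test_word2vec_text_loader(tmp_path):
    plain = tmp_path / "vecs.txt"
    plain.write_text("2 3\nfoo 1.0 2.0 3.0\nbar -1.0 0.5 0.25\n")
    v = load_word2vec_text(plain)
    assert set(v) == {"foo", "bar"}
    assert np.allclose(v["bar"], [-1.0, 0.5, 0.25])
    gz = tmp_path / "vecs.txt.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write("foo 1.0 2.0\n")  # no header dialect
    assert np.allclose(load_word2vec_text(gz)["foo"], [1.0, 2.0])
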