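"""PubTator parsing, segmentation/alignment and candidate-pair enumeration."""
from __future__ import annotations

import io
import random

import pytest

import cidrel as cr
from cidrel.corpus_io import (
    PubTatorError,
    enumerate_candidate_pairs,
    read_pubtator,
    segment_and_align,
    write_pubtator,
)
from cidrel.types import Document, EntityType, Mention


def doc_fields(doc: cr.Document):
    return (
        doc.doc_id, doc.title, doc.abstract, doc.sentences,
        [(m.char_start, m.char_end, m.surface, m.etype, m.concept_id,
          m.sentence_index, m.token_span) for m in doc.mentions],
        [(c.concept_id, c.etype, tuple(c.mention_indices)) for c in doc.concepts],
        sorted((r.chemical_id, r.disease_id, r.label) for r in doc.gold_relations),
    )


def test_empty_stream_yields_empty_corpus():
    assert len(read_pubtator(io.StringIO(""))) == 0
    assert len(read_pubtator(io.StringIO("\n\n"))) == 0


def test_two_sentence_fixture_parses_to_known_content(two_sentence_doc):
    doc = two_sentence_doc
    assert doc.n_sentences == 2
    assert len(doc.mentions) == 3
    assert len(doc.concepts) == 2
    assert len(doc.gold_relations) == 1
    assert doc.sentences[0] == ["Naloxone", "effects", "in", "rats"]
    assert doc.sentences[1] == ["Naloxone", "induced", "severe", "hypertension", "."]
    # title mention aligns to token 0 of sentence 0
    m0 = doc.mentions[0]
    assert (m0.char_start, m0.sentence_index, m0.token_span) == (0, 0, (0, 1))
    # every mention's surface equals the character slice it claims
    text = doc.text("\n")
    for m in doc.mentions:
        assert text[m.char_start:m.char_end] == m.surface
    hyp = doc.mentions[2]
    assert hyp.sentence_index == 1 and hyp.token_span == (3, 4)


def test_eight_sentence_document_structure(eight_sentence_doc):
    doc = eight_sentence_doc
    assert doc.n_sentences == 8
    assert len(doc.mentions) == 12
    assert len(doc.concepts) == 6


def test_composite_id_expansion_and_unnormalized_drop(composite_text, caplog):
    with caplog.at_level("WARNING"):
        doc = read_pubtator(io.StringIO(composite_text)).documents[0]
    # composite annotation becomes two mentions sharing one span
    chems = [m for m in doc.mentions if m.etype == EntityType.CHEMICAL]
    assert {m.concept_id for m in chems} == {"D000001", "D000002"}
    assert len({(m.char_start, m.char_end) for m in chems}) == 1
    # the unnormalized annotation is gone, with a warning
    assert all(m.concept_id != "-1" for m in doc.mentions)
    assert any("unnormalized" in r.message for r in caplog.records)
    assert len(doc.mentions) == 3


def test_roundtrip_identity(two_sentence_text, composite_text, small_corpus):
    for corpus in (
        read_pubtator(io.StringIO(two_sentence_text + "\n" + composite_text)),
        small_corpus,
    ):
        buf = io.StringIO()
        write_pubtator(corpus, buf)
        buf.seek(0)
        again = read_pubtator(buf)
        assert len(again) == len(corpus)
        for a, b in zip(corpus, again):
            assert doc_fields(a) == doc_fields(b)
        # a second cycle is byte-identical (read∘write is a fixed point)
        buf2 = io.StringIO()
        write_pubtator(again, buf2)
        assert buf2.getvalue() == buf.getvalue()


def test_offset_surface_mismatch_is_hard_error():
    bad = "1|t|Title here\n1|a|Abstract text .\n1\t0\t5\tWRONG\tChemical\tD1\n"
    with pytest.raises(PubTatorError, match="WRONG"):
        read_pubtator(io.StringIO(bad))


def test_unknown_entity_type_is_error():
    bad = "1|t|Title here\n1|a|Abstract .\n1\t0\t5\tTitle\tGene\tD1\n"
    with pytest.raises(PubTatorError, match="Gene"):
        read_pubtator(io.StringIO(bad))


def test_relation_to_absent_concept_is_skipped_with_warning(caplog):
    text = (
        "1|t|Aspirin study\n1|a|Aspirin was assessed .\n"
        "1\t0\t7\tAspirin\tChemical\tD001241\n"
        "1\tCID\tD001241\tD999999\n"
    )
    with caplog.at_level("WARNING"):
        corpus = read_pubtator(io.StringIO(text))
    assert corpus.documents[0].gold_relations == []
    assert any("unannotated" in r.message for r in caplog.records)


def test_alignment_boundary_cases():
    doc = Document(
        doc_id="x", title="One small probe here",
        abstract="",
        mentions=[Mention("x", 10, 15, "probe", EntityType.CHEMICAL, "D1")],
    )
    segment_and_align(doc)
    m = doc.mentions[0]
    assert m.sentence_index == 0 and m.token_span == (2, 3)

    doc2 = Document(
        doc_id="y", title="Probe first",
        abstract="",
        mentions=[Mention("y", 0, 5, "Probe", EntityType.CHEMICAL, "D1")],
    )
    segment_and_align(doc2)
    assert doc2.mentions[0].token_span == (0, 1)


def test_sentence_split_inside_mention_is_repaired():
    # the splitter would end a sentence after "Depot." (capitalized next
    # word); the mention forces the two fragments to merge
    title = "Injection study"
    abstract = "Patients received Depot. Medrol daily . Symptoms resolved later ."
    start = (title + "\n" + abstract).find("Depot. Medrol")
    doc = Document(
        doc_id="z", title=title, abstract=abstract,
        mentions=[Mention("z", start, start + len("Depot. Medrol"),
                          "Depot. Medrol", EntityType.CHEMICAL, "D1")],
    )
    segment_and_align(doc)
    m = doc.mentions[0]
    assert m.sentence_index == 1  # title, merged sentence, tail sentence
    assert doc.n_sentences == 3
    toks = doc.sentences[1]
    assert toks[m.token_span[0]:m.token_span[1]] == ["Depot", ".", "Medrol"]


def test_candidate_pairs_cross_product():
    def mk(chems, diss, gold):
        mentions, concepts = [], []
        for i, (cid, et) in enumerate(
            [(c, EntityType.CHEMICAL) for c in chems]
            + [(d, EntityType.DISEASE) for d in diss]
        ):
            mentions.append(Mention("d", 10 * i, 10 * i + 5, "xxxxx", et, cid,
                                    sentence_index=0, token_span=(0, 1)))
            concepts.append(cr.EntityConcept(cid, et, [i]))
        rels = [cr.RelationFact("d", c, d, 1) for c, d in gold]
        return Document("d", "t", "a", sentences=[["xxxxx"]], mentions=mentions,
                        concepts=concepts, gold_relations=rels)

    assert enumerate_candidate_pairs(mk([], ["D9"], [])) == []
    pairs = enumerate_candidate_pairs(
        mk(["C2", "C1"], ["D1", "D3", "D2"], [("C1", "D2")])
    )
    assert len(pairs) == 6
    assert sum(y for _, _, y in pairs) == 1
    assert pairs == sorted(pairs)  # lexicographic by (chemical, disease)

    # order depends only on concept ids, not mention order
    doc = mk(["C2", "C1"], ["D1", "D3", "D2"], [("C1", "D2")])
    rng = random.Random(0)
    perm = list(range(len(doc.mentions)))
    rng.shuffle(perm)
    doc.mentions = [doc.mentions[i] for i in perm]
    inv = {old: new for new, old in enumerate(perm)}
    for c in doc.concepts:
        c.mention_indices = [inv[i] for i in c.mention_indices]
    assert enumerate_candidate_pairs(doc) == pairs


def test_candidate_pair_invariants_on_synthetic(small_corpus):
    for doc in small_corpus:
        pairs = enumerate_candidate_pairs(doc)
        n_c = len(doc.concepts_of_type(EntityType.CHEMICAL))
        n_d = len(doc.concepts_of_type(EntityType.DISEASE))
        assert len(pairs) == n_c * n_d
        gold = {(r.chemical_id, r.disease_id) for r in doc.gold_relations}
        assert gold <= {(c, d) for c, d, _ in pairs}
        # N preserved by segmentation: every annotation is aligned
        assert all(m.aligned for m in doc.mentions)
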