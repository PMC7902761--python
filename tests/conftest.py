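"""Shared fixtures: hand-written PubTator documents and tiny corpora.

All fixtures are built programmatically; character offsets of the
hand-written documents are computed from the text itself so the fixtures
stay valid by construction.
"""
from __future__ import annotations

import io

import numpy as np
import pytest

import cidrel as cr


def pubtator_block(doc_id: str, title: str, abstract: str,
                   annotations: list[tuple[str, str, str, int]],
                   relations: list[tuple[str, str]]) -> str:
    """Assemble one PubTator block; each annotation is
    (surface, etype, mesh, occurrence_index) and offsets are located in
    ``title + "\\n" + abstract`` automatically."""
    text = title + "\n" + abstract
    lines = [f"{doc_id}|t|{title}", f"{doc_id}|a|{abstract}"]
    rows = []
    for surface, etype, mesh, occurrence in annotations:
        start = -1
        for _ in range(occurrence + 1):
            start = text.find(surface, start + 1)
            if start < 0:
                raise AssertionError(f"fixture bug: {surface!r} #{occurrence}")
        rows.append((start, start + len(surface), surface, etype, mesh))
    rows.sort()
    for start, end, surface, etype, mesh in rows:
        lines.append(f"{doc_id}\t{start}\t{end}\t{surface}\t{etype}\t{mesh}")
    for chem, dis in relations:
        lines.append(f"{doc_id}\tCID\t{chem}\t{dis}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_sentence_text() -> str:
    """Two sentences (title + one abstract sentence), 3 mentions, 2
    concepts, 1 document-level relation."""
    return pubtator_block(
        "10001",
        "Naloxone effects in rats",
        "Naloxone induced severe hypertension .",
        [
            ("Naloxone", "Chemical", "D009270", 0),
            ("Naloxone", "Chemical", "D009270", 1),
            ("hypertension", "Disease", "D006973", 0),
        ],
        [("D009270", "D006973")],
    )


@pytest.fixture
def two_sentence_doc(two_sentence_text) -> cr.Document:
    return cr.read_pubtator(io.StringIO(two_sentence_text)).documents[0]


@pytest.fixture
def eight_sentence_text() -> str:
    """A document with 8 sentences and 12 mentions over 6 concepts
    (3 chemicals, 3 diseases) — the canonical size used for graph checks."""
    title = "Chema in experimental models"
    sents = [
        "Chema induced Disa .",
        "Disa and Chemb were observed .",
        "Chemb was administered .",
        "Disb appeared in several animals .",
        "Chemc and Disc were observed .",
        "Chema was given again .",
        "Disb and Chemc were observed .",
    ]
    abstract = " ".join(sents)
    ann = [
        ("Chema", "Chemical", "C0001", 0),
        ("Chema", "Chemical", "C0001", 1),
        ("Chema", "Chemical", "C0001", 2),
        ("Chemb", "Chemical", "C0002", 0),
        ("Chemb", "Chemical", "C0002", 1),
        ("Chemc", "Chemical", "C0003", 0),
        ("Chemc", "Chemical", "C0003", 1),
        ("Disa", "Disease", "C1001", 0),
        ("Disa", "Disease", "C1001", 1),
        ("Disb", "Disease", "C1002", 0),
        ("Disb", "Disease", "C1002", 1),
        ("Disc", "Disease", "C1003", 0),
    ]
    return pubtator_block("10002", title, abstract, ann, [("C0001", "C1001")])


@pytest.fixture
def eight_sentence_doc(eight_sentence_text) -> cr.Document:
    return cr.read_pubtator(io.StringIO(eight_sentence_text)).documents[0]


@pytest.fixture
def composite_text() -> str:
    """Composite MeSH annotation (two ids, one span) plus an unnormalized
    ``-1`` annotation that must be dropped."""
    return pubtator_block(
        "10003",
        "Mixture study",
        "Carbimazole and thiamazole induced rash . Pruritus was reported .",
        [
            ("Carbimazole and thiamazole", "Chemical", "D000001|D000002", 0),
            ("rash", "Disease", "D012871", 0),
            ("Pruritus", "Disease", "-1", 0),
        ],
        [("D000001", "D012871")],
    )


@pytest.fixture
def small_corpus() -> cr.Corpus:
    return cr.generate_corpus(cr.SynthConfig(n_docs=12, seed=7))


@pytest.fixture
def tiny_model_setup():
    """A small trained-size (but untrained) model over a 3-document corpus."""
    corpus = cr.generate_corpus(cr.SynthConfig(n_docs=3, seed=3))
    cfg = cr.ModelConfig(d_w=6, d_h=6, d_t=3, n_gcn_layers=2)
    vocab = [t for d in corpus for s in d.sentences for t in s]
    model = cr.Model.init(vocab, cfg, seed=0)
    return corpus, model
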