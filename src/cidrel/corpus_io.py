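"""PubTator corpus I/O, sentence segmentation and mention–token alignment.

The PubTator dialect handled here::

    PMID|t|Title text
    PMID|a|Abstract text
    PMID<TAB>start<TAB>end<TAB>surface<TAB>Chemical|Disease<TAB>MeSH
    PMID<TAB>CID<TAB>chemical_MeSH<TAB>disease_MeSH
    <blank line between documents>

Character offsets index into ``title + separator + abstract`` (0-based,
half-open). The separator is configurable (default ``"\\n"``); offsets are
always validated against the annotated surface strings, so a corpus using
the other convention fails loudly rather than silently misaligning.

Composite concept annotations (``D000001|D000002``) are expanded into one
mention per identifier sharing the span; unnormalized annotations (``-1``)
are dropped with a warning, since the classification unit is the normalized
concept pair.
"""
from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, TextIO, Union

from .types import (
    Corpus,
    Document,
    EntityConcept,
    EntityType,
    Mention,
    RelationFact,
)

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, TextIO]


class PubTatorError(ValueError):
    """Raised on malformed or internally inconsistent PubTator input."""


# ---------------------------------------------------------------------------
# Tokenization (pluggable; defaults are a Punkt-style sentence splitter and
# a Treebank-style word tokenizer)
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+(?:[-'’/]\w+)*|[^\w\s]")

#: abbreviations that must not terminate a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "fig", "figs", "dr", "mr", "mrs", "ms",
    "prof", "al", "ca", "cf", "approx", "resp", "no", "vol", "st",
}

_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def word_tokenize_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of word tokens: alphanumeric runs (with internal
    hyphen/apostrophe/slash) or single punctuation marks."""
    return [m.span() for m in _WORD_RE.finditer(text)]


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences within ``text``.

    Boundaries are placed after ``.!?`` runs followed by whitespace, unless
    the preceding token is a known abbreviation, a single capital initial,
    or the following character is lowercase (Punkt-style heuristics).
    """
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end()
        prev = text[: m.start()].rstrip()
        last_word = prev.split()[-1].lower() if prev.split() else ""
        last_word = last_word.rstrip(".")
        if last_word in _ABBREVIATIONS:
            continue
        if len(last_word) == 1 and last_word.isalpha():
            continue  # single initial, e.g. "J. Smith"
        nxt = text[end:].lstrip()
        if nxt and nxt[0].islower():
            continue
        boundaries.append(end)
    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        seg = text[start:b]
        if seg.strip():
            s = start + (len(seg) - len(seg.lstrip()))
            e = start + len(seg.rstrip())
            spans.append((s, e))
        start = b
    tail = text[start:]
    if tail.strip():
        s = start + (len(tail) - len(tail.lstrip()))
        e = start + len(tail.rstrip())
        spans.append((s, e))
    return spans


@dataclass
class ReaderConfig:
    """PubTator dialect and tokenization configuration.

    ``separator`` joins title and abstract for offset computation;
    ``"\\n"`` is the default convention and is validated against every
    annotated surface string.
    """

    separator: str = "\n"
    sentence_splitter: Callable[[str], list[tuple[int, int]]] = sentence_spans
    word_tokenizer: Callable[[str], list[tuple[int, int]]] = word_tokenize_spans

    def describe(self) -> dict:
        return {
            "separator": self.separator,
            "sentence_splitter": getattr(
                self.sentence_splitter, "__name__", repr(self.sentence_splitter)
            ),
            "word_tokenizer": getattr(
                self.word_tokenizer, "__name__", repr(self.word_tokenizer)
            ),
        }


DEFAULT_CONFIG = ReaderConfig()


# ---------------------------------------------------------------------------
# Segmentation and alignment
# ---------------------------------------------------------------------------

def segment_and_align(doc: Document, config: ReaderConfig = DEFAULT_CONFIG) -> Document:
    """Split a document into tokenized sentences and align every mention.

    The title is always the first sentence. A proposed sentence boundary
    falling strictly inside a mention span is suppressed (the two fragments
    are merged) so that every mention lives in exactly one sentence.
    Mentions are assigned ``sentence_index`` and a half-open ``token_span``
    of the tokens overlapping their character span.
    """
    text = doc.text(config.separator)
    title_end = len(doc.title)
    abstract_offset = title_end + len(config.separator)

    spans: list[tuple[int, int]] = []
    if doc.title.strip():
        spans.append((0, len(doc.title.rstrip())))
    for s, e in config.sentence_splitter(doc.abstract):
        spans.append((s + abstract_offset, e + abstract_offset))
    if not spans:
        raise PubTatorError(f"document {doc.doc_id} has no text")

    spans = _repair_boundaries(spans, doc.mentions, doc.doc_id)

    sentences: list[list[str]] = []
    token_spans: list[list[tuple[int, int]]] = []
    for s, e in spans:
        tspans = [(ts + s, te + s) for ts, te in config.word_tokenizer(text[s:e])]
        if not tspans:
            continue
        sentences.append([text[a:b] for a, b in tspans])
        token_spans.append(tspans)
    spans = [(ts[0][0], ts[-1][1]) for ts in token_spans]

    for m in doc.mentions:
        m.sentence_index = -1
        for si, (s, e) in enumerate(spans):
            if m.char_start >= s and m.char_end <= e:
                m.sentence_index = si
                break
        if m.sentence_index < 0:
            raise PubTatorError(
                f"document {doc.doc_id}: mention '{m.surface}' at "
                f"[{m.char_start},{m.char_end}) not contained in any sentence"
            )
        toks = token_spans[m.sentence_index]
        first = last = -1
        for ti, (a, b) in enumerate(toks):
            if b > m.char_start and a < m.char_end:
                if first < 0:
                    first = ti
                last = ti
        if first < 0:
            raise PubTatorError(
                f"document {doc.doc_id}: mention '{m.surface}' at "
                f"[{m.char_start},{m.char_end}) aligns to no token"
            )
        m.token_span = (first, last + 1)

    doc.sentences = sentences
    return doc


def _repair_boundaries(
    spans: list[tuple[int, int]],
    mentions: Iterable[Mention],
    doc_id: str,
) -> list[tuple[int, int]]:
    """Merge consecutive sentence spans whenever a mention straddles them."""
    spans = list(spans)
    changed = True
    while changed:
        changed = False
        for m in mentions:
            for i in range(len(spans) - 1):
                s0, e0 = spans[i]
                s1, e1 = spans[i + 1]
                if m.char_start < e0 and m.char_end > s1:
                    spans[i : i + 2] = [(s0, e1)]
                    changed = True
                    break
            if changed:
                break
    return spans


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_pubtator(
    source: PathOrStream, config: ReaderConfig = DEFAULT_CONFIG, split_tag: str = "synthetic"
) -> Corpus:
    """Parse a PubTator file or stream into a fully aligned :class:`Corpus`."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_pubtator(fh, config, split_tag)

    documents: list[Document] = []
    block: list[str] = []
    for raw in source:
        line = raw.rstrip("\n")
        if line.strip() == "":
            if block:
                documents.append(_parse_block(block, config))
                block = []
        else:
            block.append(line)
    if block:
        documents.append(_parse_block(block, config))
    return Corpus(documents=documents, split_tag=split_tag)


def _parse_block(lines: list[str], config: ReaderConfig) -> Document:
    doc_id = None
    title = abstract = ""
    ann_rows: list[tuple[int, int, str, str, str]] = []
    rel_rows: list[tuple[str, str]] = []

    for line in lines:
        if "|t|" in line and "\t" not in line.split("|t|")[0]:
            doc_id_t, title = line.split("|t|", 1)
            doc_id = doc_id or doc_id_t
            continue
        if "|a|" in line and "\t" not in line.split("|a|")[0]:
            doc_id_a, abstract = line.split("|a|", 1)
            doc_id = doc_id or doc_id_a
            continue
        fields = line.split("\t")
        if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
            ann_rows.append(
                (int(fields[1]), int(fields[2]), fields[3], fields[4], fields[5])
            )
        elif len(fields) == 4 and fields[1].upper() == "CID":
            rel_rows.append((fields[2], fields[3]))
        else:
            raise PubTatorError(f"unrecognized PubTator line: {line!r}")

    if doc_id is None:
        raise PubTatorError(f"block without title/abstract lines: {lines[:2]!r}")

    text = title + config.separator + abstract
    mentions: list[Mention] = []
    for start, end, surface, etype_s, mesh in ann_rows:
        try:
            etype = EntityType(etype_s)
        except ValueError:
            raise PubTatorError(
                f"document {doc_id}: unknown entity type {etype_s!r}"
            ) from None
        if text[start:end] != surface:
            raise PubTatorError(
                f"document {doc_id}: offsets [{start},{end}) yield "
                f"{text[start:end]!r}, annotation says {surface!r}"
            )
        for cid in mesh.split("|"):
            cid = cid.strip()
            if cid == "-1" or cid == "":
                logger.warning(
                    "document %s: dropping unnormalized annotation %r at [%d,%d)",
                    doc_id, surface, start, end,
                )
                continue
            mentions.append(
                Mention(
                    doc_id=doc_id,
                    char_start=start,
                    char_end=end,
                    surface=surface,
                    etype=etype,
                    concept_id=cid,
                )
            )

    concepts = _group_concepts(doc_id, mentions)
    concept_ids = {c.concept_id: c for c in concepts}

    relations: list[RelationFact] = []
    seen_pairs: set[tuple[str, str]] = set()
    for chem, dis in rel_rows:
        if chem not in concept_ids or dis not in concept_ids:
            logger.warning(
                "document %s: relation (%s, %s) references an unannotated "
                "concept; skipping", doc_id, chem, dis,
            )
            continue
        if concept_ids[chem].etype != EntityType.CHEMICAL:
            raise PubTatorError(
                f"document {doc_id}: relation chemical {chem} is annotated as "
                f"{concept_ids[chem].etype.value}"
            )
        if concept_ids[dis].etype != EntityType.DISEASE:
            raise PubTatorError(
                f"document {doc_id}: relation disease {dis} is annotated as "
                f"{concept_ids[dis].etype.value}"
            )
        if (chem, dis) in seen_pairs:
            continue
        seen_pairs.add((chem, dis))
        relations.append(RelationFact(doc_id, chem, dis, 1))

    doc = Document(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        mentions=mentions,
        concepts=concepts,
        gold_relations=relations,
    )
    segment_and_align(doc, config)
    doc.validate()
    return doc


def _group_concepts(doc_id: str, mentions: list[Mention]) -> list[EntityConcept]:
    order: dict[str, EntityConcept] = {}
    for i, m in enumerate(mentions):
        if m.concept_id in order:
            c = order[m.concept_id]
            if c.etype != m.etype:
                raise PubTatorError(
                    f"document {doc_id}: concept {m.concept_id} annotated with "
                    f"conflicting entity types {c.etype.value}/{m.etype.value}"
                )
            c.mention_indices.append(i)
        else:
            order[m.concept_id] = EntityConcept(m.concept_id, m.etype, [i])
    return list(order.values())


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pubtator(corpus: Corpus, sink: PathOrStream) -> None:
    """Serialize a corpus back to PubTator text; ``read(write(c)) == c``."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_pubtator(corpus, fh)
        return

    for doc in corpus:
        sink.write(f"{doc.doc_id}|t|{doc.title}\n")
        sink.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            sink.write(
                f"{doc.doc_id}\t{m.char_start}\t{m.char_end}\t{m.surface}\t"
                f"{m.etype.value}\t{m.concept_id}\n"
            )
        for r in doc.gold_relations:
            if r.label == 1:
                sink.write(f"{doc.doc_id}\tCID\t{r.chemical_id}\t{r.disease_id}\n")
        sink.write("\n")


# ---------------------------------------------------------------------------
# Candidate pairs
# ---------------------------------------------------------------------------

def enumerate_candidate_pairs(doc: Document) -> list[tuple[str, str, int]]:
    """All chemical × disease concept pairs with closed-world binary labels.

    Every unannotated pair is a negative. Order is deterministic:
    lexicographic by (chemical id, disease id), independent of mention order.
    """
    chems = sorted(c.concept_id for c in doc.concepts_of_type(EntityType.CHEMICAL))
    diss = sorted(c.concept_id for c in doc.concepts_of_type(EntityType.DISEASE))
    gold = {
        (r.chemical_id, r.disease_id) for r in doc.gold_relations if r.label == 1
    }
    return [
        (ch, di, 1 if (ch, di) in gold else 0) for ch in chems for di in diss
    ]


def write_predictions_tsv(predictions, sink: PathOrStream) -> None:
    """Dump scored pairs as ``doc_id  chemical_id  disease_id  score  label``."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_predictions_tsv(predictions, fh)
        return
    for p in predictions:
        sink.write(
            f"{p.doc_id}\t{p.chemical_id}\t{p.disease_id}\t{p.score:.6f}\t{p.label}\n"
        )


def read_predictions_tsv(source: PathOrStream):
    from .types import ScoredRelation

    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_predictions_tsv(fh)
    out = []
    for line in source:
        if not line.strip():
            continue
        doc_id, chem, dis, score, label = line.rstrip("\n").split("\t")
        out.append(ScoredRelation(doc_id, chem, dis, float(score), int(label)))
    return out
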