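"""Core document model for document-level chemical–disease relation extraction.

A document is a title plus abstract with character-offset entity-mention
annotations. Mentions are grouped into *entity concepts* by their normalized
MeSH identifier; relations (chemical-induced disease) hold between concept
pairs at the document level, not between individual mentions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum


class EntityType(str, Enum):
    CHEMICAL = "Chemical"
    DISEASE = "Disease"


@dataclass
class Mention:
    """A single annotated text span.

    ``char_start``/``char_end`` are 0-based half-open offsets into the
    document text (title + separator + abstract).  ``sentence_index`` and
    ``token_span`` are filled in by sentence segmentation / token alignment.
    """

    doc_id: str
    char_start: int
    char_end: int
    surface: str
    etype: EntityType
    concept_id: str
    sentence_index: int = -1
    token_span: tuple[int, int] = (-1, -1)

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(
                f"mention {self.doc_id}:{self.char_start}-{self.char_end} "
                "has empty or inverted span"
            )
        self.etype = EntityType(self.etype)

    @property
    def aligned(self) -> bool:
        return self.sentence_index >= 0 and self.token_span[0] >= 0


@dataclass
class EntityConcept:
    """A normalized concept: all mentions in a document sharing one MeSH id."""

    concept_id: str
    etype: EntityType
    mention_indices: list[int]

    def __post_init__(self) -> None:
        if not self.mention_indices:
            raise ValueError(f"concept {self.concept_id} has no mentions")
        self.etype = EntityType(self.etype)


@dataclass(frozen=True)
class RelationFact:
    """A document-level chemical-induced disease assertion (label 1) or its
    absence (label 0) between two concept identifiers."""

    doc_id: str
    chemical_id: str
    disease_id: str
    label: int = 1


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    sentences: list[list[str]] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    concepts: list[EntityConcept] = field(default_factory=list)
    gold_relations: list[RelationFact] = field(default_factory=list)

    # -- derived views -------------------------------------------------
    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    def text(self, separator: str = "\n") -> str:
        return self.title + separator + self.abstract

    def concept(self, concept_id: str) -> EntityConcept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(f"concept {concept_id} not in document {self.doc_id}")

    def concepts_of_type(self, etype: EntityType) -> list[EntityConcept]:
        return [c for c in self.concepts if c.etype == etype]

    def sentences_of_concept(self, concept_id: str) -> set[int]:
        """Indices of sentences containing at least one mention of a concept."""
        c = self.concept(concept_id)
        return {self.mentions[i].sentence_index for i in c.mention_indices}

    def validate(self) -> None:
        seen = set()
        for c in self.concepts:
            if c.concept_id in seen:
                raise ValueError(f"duplicate concept {c.concept_id} in {self.doc_id}")
            seen.add(c.concept_id)
            for i in c.mention_indices:
                m = self.mentions[i]
                if m.concept_id != c.concept_id or m.etype != c.etype:
                    raise ValueError(
                        f"mention {i} disagrees with concept {c.concept_id}"
                    )
        pair_keys = set()
        for r in self.gold_relations:
            key = (r.chemical_id, r.disease_id)
            if key in pair_keys:
                raise ValueError(f"duplicate relation {key} in {self.doc_id}")
            pair_keys.add(key)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    split_tag: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def get(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


@dataclass(frozen=True)
class ScoredRelation:
    """A model prediction for one candidate concept pair."""

    doc_id: str
    chemical_id: str
    disease_id: str
    score: float  # p(r = 1)
    label: int  # predicted label under the decision threshold


__all__ = [
    "EntityType",
    "Mention",
    "EntityConcept",
    "RelationFact",
    "Document",
    "Corpus",
    "ScoredRelation",
    "replace",
]
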