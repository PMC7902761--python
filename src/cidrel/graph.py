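"""Heterogeneous document-graph construction.

One graph per document over N mention + R entity + T sentence nodes, with a
binary symmetric adjacency built from five natural-association rules:

* MM — two mentions appearing in the same sentence;
* SS — every pair of sentence nodes (the sentence subgraph is a clique,
  carrying global document information);
* MS — each mention to the sentence containing it;
* ME — each mention to its normalized entity concept;
* ES — each entity to every sentence in which one of its mentions appears;

plus self-loops on all nodes, so a node's own representation participates
in its convolutional update. Edges are unweighted and untyped at the
convolution level (a single adjacency); the per-edge rule labels are kept
for inspection and validity checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO, Union

import numpy as np

from .encoder import node_layout
from .types import Document

EDGE_MM = "MM"
EDGE_SS = "SS"
EDGE_MS = "MS"
EDGE_ME = "ME"
EDGE_ES = "ES"
EDGE_SELF = "SELF"

#: which node-kind pairs each rule may connect (unordered)
_LEGAL = {
    EDGE_MM: {"mention"},
    EDGE_SS: {"sentence"},
    EDGE_MS: {"mention", "sentence"},
    EDGE_ME: {"mention", "entity"},
    EDGE_ES: {"entity", "sentence"},
}


@dataclass
class DocumentGraph:
    A: np.ndarray  # (n, n) binary symmetric with unit diagonal
    kinds: list[str]
    mention_rows: dict[int, int]
    entity_rows: dict[str, int]
    sentence_rows: dict[int, int]
    edge_types: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def edge_count(self, edge_type: str) -> int:
        return sum(1 for t in self.edge_types.values() if t == edge_type)

    def validate(self) -> None:
        A = self.A
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency is not symmetric")
        if not np.all(np.diag(A) == 1):
            raise ValueError("missing self-loops")
        if not np.all((A == 0) | (A == 1)):
            raise ValueError("adjacency is not binary")
        listed = set()
        for (i, j), t in self.edge_types.items():
            if A[i, j] != 1:
                raise ValueError(f"typed edge ({i},{j}) absent from adjacency")
            if {self.kinds[i], self.kinds[j]} != _LEGAL[t]:
                raise ValueError(
                    f"edge ({i},{j}) typed {t} connects "
                    f"{self.kinds[i]}–{self.kinds[j]}"
                )
            listed.add((i, j))
            listed.add((j, i))
        off_diag = {(i, j) for i, j in zip(*np.nonzero(A)) if i != j}
        if off_diag != listed:
            raise ValueError("adjacency and edge-type map disagree")


def build_adjacency(doc: Document) -> DocumentGraph:
    """Apply the five connection rules to an aligned document."""
    for m in doc.mentions:
        if m.sentence_index < 0:
            raise ValueError(
                f"mention '{m.surface}' in {doc.doc_id} has no sentence "
                "assignment; run segment_and_align first"
            )
    kinds, mention_rows, entity_rows, sentence_rows = node_layout(doc)
    n = len(kinds)
    A = np.eye(n)
    edge_types: dict[tuple[int, int], str] = {}

    def connect(i: int, j: int, etype: str) -> None:
        if i == j:
            return
        A[i, j] = A[j, i] = 1.0
        edge_types[(min(i, j), max(i, j))] = etype

    # MM: same-sentence mention pairs (regardless of concept identity)
    for i, mi in enumerate(doc.mentions):
        for j in range(i + 1, len(doc.mentions)):
            if doc.mentions[j].sentence_index == mi.sentence_index:
                connect(mention_rows[i], mention_rows[j], EDGE_MM)
    # SS: sentence clique
    T = doc.n_sentences
    for s in range(T):
        for t in range(s + 1, T):
            connect(sentence_rows[s], sentence_rows[t], EDGE_SS)
    # MS: mention to containing sentence
    for i, m in enumerate(doc.mentions):
        connect(mention_rows[i], sentence_rows[m.sentence_index], EDGE_MS)
    # ME: mention to its concept
    for c in doc.concepts:
        for i in c.mention_indices:
            connect(mention_rows[i], entity_rows[c.concept_id], EDGE_ME)
    # ES: entity to every sentence holding one of its mentions
    for c in doc.concepts:
        for s in {doc.mentions[i].sentence_index for i in c.mention_indices}:
            connect(entity_rows[c.concept_id], sentence_rows[s], EDGE_ES)

    graph = DocumentGraph(A, kinds, mention_rows, entity_rows, sentence_rows, edge_types)
    return graph


def make_fully_connected(graph: DocumentGraph) -> DocumentGraph:
    """Ablation variant: all-ones adjacency of the same size; node maps are
    preserved and per-rule edge labels dropped (every pair is connected)."""
    n = graph.n_nodes
    return DocumentGraph(
        np.ones((n, n)),
        list(graph.kinds),
        dict(graph.mention_rows),
        dict(graph.entity_rows),
        dict(graph.sentence_rows),
        edge_types={},
    )


def normalize_adjacency(A: np.ndarray, mode: str = "none") -> np.ndarray:
    """Optional degree normalization of a self-looped adjacency.

    ``none`` leaves A untouched (the convolution as printed);
    ``sym`` gives D^{-1/2} A D^{-1/2}; ``row`` gives D^{-1} A.
    Self-loops guarantee strictly positive degrees.
    """
    if mode == "none":
        return A
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero-degree node; adjacency must include self-loops")
    if mode == "sym":
        d = 1.0 / np.sqrt(deg)
        return A * d[:, None] * d[None, :]
    if mode == "row":
        return A / deg[:, None]
    raise ValueError(f"unknown normalization mode {mode!r}")


def expected_edge_counts(doc: Document) -> dict[str, int]:
    """Closed-form edge counts implied by the five rules (used as an
    independent check of :func:`build_adjacency`)."""
    N, T = len(doc.mentions), doc.n_sentences
    per_sentence: dict[int, int] = {}
    for m in doc.mentions:
        per_sentence[m.sentence_index] = per_sentence.get(m.sentence_index, 0) + 1
    mm = sum(k * (k - 1) // 2 for k in per_sentence.values())
    es = sum(
        len({doc.mentions[i].sentence_index for i in c.mention_indices})
        for c in doc.concepts
    )
    return {
        EDGE_MM: mm,
        EDGE_SS: T * (T - 1) // 2,
        EDGE_MS: N,
        EDGE_ME: N,
        EDGE_ES: es,
    }


def write_edge_list(graph: DocumentGraph, sink: Union[str, Path, TextIO]) -> None:
    """Debug export: one ``node_i  node_j  edge_type`` line per edge."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_edge_list(graph, fh)
        return
    for i in range(graph.n_nodes):
        sink.write(f"{i}\t{i}\t{EDGE_SELF}\n")
    for (i, j), t in sorted(graph.edge_types.items()):
        sink.write(f"{i}\t{j}\t{t}\n")
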