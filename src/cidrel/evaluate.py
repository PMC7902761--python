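"""Concept-pair evaluation: micro-averaged P/R/F1 with an intra-/inter-sentence
breakdown, plus the ablation harness.

A concept pair is *intra-sentence* if at least one sentence contains a
mention of both concepts, and *inter-sentence* otherwise — the standard
convention for document-level chemical–disease relation evaluation. Pair
identity is always at the concept (MeSH id) level, never the mention level.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import Corpus, Document, ScoredRelation

INTRA = "intra"
INTER = "inter"


def split_intra_inter(doc: Document, pair: tuple[str, str]) -> str:
    """Classify a (chemical_id, disease_id) pair as intra- or inter-sentence.

    Intra iff some single sentence contains >= 1 mention of each concept.
    Raises ``KeyError`` if either concept is absent from the document.
    """
    chem_id, dis_id = pair
    chem_sents = doc.sentences_of_concept(chem_id)
    dis_sents = doc.sentences_of_concept(dis_id)
    return INTRA if chem_sents & dis_sents else INTER


@dataclass
class PRF:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass
class EvalReport:
    overall: PRF = field(default_factory=PRF)
    intra: PRF = field(default_factory=PRF)
    inter: PRF = field(default_factory=PRF)
    per_document: dict[str, PRF] | None = None

    def as_dict(self) -> dict:
        d = {
            "overall": self.overall.as_dict(),
            "intra": self.intra.as_dict(),
            "inter": self.inter.as_dict(),
        }
        if self.per_document is not None:
            d["per_document"] = {k: v.as_dict() for k, v in self.per_document.items()}
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), **kw)


def evaluate(
    gold_corpus: Corpus,
    predictions: Iterable[ScoredRelation],
    per_document: bool = False,
) -> EvalReport:
    """Micro-averaged concept-pair evaluation against gold document relations.

    ``predictions`` are scored pairs; only those with predicted label 1
    count as system positives. A prediction for a document absent from the
    gold corpus is an error. With no positive predictions, precision is
    reported as 0 by convention.
    """
    gold_by_doc: dict[str, set[tuple[str, str]]] = {}
    for doc in gold_corpus:
        gold_by_doc[doc.doc_id] = {
            (r.chemical_id, r.disease_id)
            for r in doc.gold_relations
            if r.label == 1
        }

    pred_by_doc: dict[str, set[tuple[str, str]]] = {d: set() for d in gold_by_doc}
    for p in predictions:
        if p.doc_id not in gold_by_doc:
            raise KeyError(f"prediction for unknown document {p.doc_id}")
        if p.label == 1:
            pred_by_doc[p.doc_id].add((p.chemical_id, p.disease_id))

    report = EvalReport(per_document={} if per_document else None)
    for doc in gold_corpus:
        gold = gold_by_doc[doc.doc_id]
        pred = pred_by_doc[doc.doc_id]
        doc_prf = PRF()
        for pair in gold | pred:
            kind = split_intra_inter(doc, pair)
            block = report.intra if kind == INTRA else report.inter
            if pair in gold and pair in pred:
                block.tp += 1
                report.overall.tp += 1
                doc_prf.tp += 1
            elif pair in pred:
                block.fp += 1
                report.overall.fp += 1
                doc_prf.fp += 1
            else:
                block.fn += 1
                report.overall.fn += 1
                doc_prf.fn += 1
        if per_document:
            report.per_document[doc.doc_id] = doc_prf
    return report


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

def ablation_cells(
    base_model_config,
    variants: Sequence[str] = ("full", "fully_connected", "no_gating", "no_aggregation"),
    grid_modes: Sequence[str] = (),
    grid_layers: Sequence[int] = (),
) -> dict:
    """Model configurations for each ablation variant / grid cell.

    ``no_aggregation`` bypasses the graph layers entirely (the classifier
    scores the encoder-only entity nodes); ``no_gating`` keeps the stack but
    uses plain convolutions; ``fully_connected`` replaces the document graph
    with an all-ones adjacency.
    """
    from dataclasses import replace as _replace

    cells: dict = {}
    for v in variants:
        if v == "full":
            cells[v] = base_model_config
        elif v == "fully_connected":
            cells[v] = _replace(base_model_config, fully_connected=True)
        elif v == "no_gating":
            cells[v] = _replace(base_model_config, gcn_mode="plain")
        elif v == "no_aggregation":
            cells[v] = _replace(base_model_config, n_gcn_layers=0)
        else:
            raise ValueError(f"unknown ablation variant {v!r}")
    for mode in grid_modes:
        for L in grid_layers:
            cells[f"{mode}_L{L}"] = _replace(
                base_model_config, gcn_mode=mode, n_gcn_layers=L
            )
    return cells


def ablation_suite(
    corpus_train: Corpus,
    corpus_eval: Corpus,
    base_train_config=None,
    base_model_config=None,
    variants: Sequence[str] = ("full", "fully_connected", "no_gating", "no_aggregation"),
    grid_modes: Sequence[str] = (),
    grid_layers: Sequence[int] = (),
    seeds: Sequence[int] = (0,),
    corpus_dev: Corpus | None = None,
) -> dict[str, list[EvalReport]]:
    """Train/evaluate the standard ablation variants plus an optional
    connection-mechanism × depth grid; one report per (cell, seed).
    ``corpus_dev``, when given, drives early stopping / checkpoint choice.

    Variants:
      * ``full``            — gated graph convolutions on the document graph
      * ``fully_connected`` — the document graph replaced by an all-ones
        adjacency (tests the value of the heterogeneous structure)
      * ``no_gating``       — plain graph convolutions, no gate
      * ``no_aggregation``  — the graph layers bypassed entirely: the
        classifier scores the encoder-only entity nodes
    """
    from .model import ModelConfig
    from .train import TrainConfig, train, predict
    from dataclasses import replace as _replace

    base_train_config = base_train_config or TrainConfig()
    base_model_config = base_model_config or ModelConfig()
    cells = ablation_cells(base_model_config, variants, grid_modes, grid_layers)

    results: dict[str, list[EvalReport]] = {}
    for name, mcfg in cells.items():
        results[name] = []
        for seed in seeds:
            tcfg = _replace(base_train_config, seed=seed)
            try:
                model = train(corpus_train, corpus_dev, tcfg, model_config=mcfg)
            except RuntimeError:
                # divergence (non-finite loss) counts as a failed cell
                results[name].append(EvalReport())
                continue
            preds = predict(model, corpus_eval)
            results[name].append(evaluate(corpus_eval, preds))
    return results


def ablation_table(results: dict[str, list[EvalReport]]) -> str:
    """Render ablation results as a TSV with 3-block F1 medians over seeds."""
    import statistics

    lines = ["variant\tn_seeds\tf1\tintra_f1\tinter_f1"]
    for name, reports in results.items():
        f1 = statistics.median(r.overall.f1 for r in reports)
        fi = statistics.median(r.intra.f1 for r in reports)
        fx = statistics.median(r.inter.f1 for r in reports)
        lines.append(f"{name}\t{len(reports)}\t{f1:.4f}\t{fi:.4f}\t{fx:.4f}")
    return "\n".join(lines) + "\n"
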