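"""Bilinear pair scoring, document-level negative log-likelihood, and the
SGD training loop.

Training follows a closed-world convention: every chemical × disease
concept pair of a document that is not annotated as related is a negative
example. The loss is the summed negative log-likelihood of the gold labels
over all candidate pairs of the documents in a batch, minimized with
(momentum) SGD under global-norm gradient clipping. The checkpoint with
the best monitored F1 (dev set if given, else training set) is returned.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _autodiff as F
from ._autodiff import SGD, Tensor, clip_gradients, value
from .evaluate import evaluate
from .model import DocumentCache, Model, ModelConfig
from .types import Corpus, ScoredRelation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (the reference work specifies only "SGD";
    the remaining values are this package's defaults)."""

    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 100
    seed: int = 0
    batch_docs: int = 1
    clip_norm: float = 5.0
    patience: int = 10
    stop_f1: float = 1.0  # stop early once the monitored F1 reaches this
    negative_subsample: float | None = None  # keep-rate for negative pairs
    threshold: float = 0.5


def score_pair(e_i, e_j, W_cls):
    """Probability vector over the two labels for one (chemical, disease)
    entity-representation pair: softmax of the bilinear logits."""
    e_i2 = np.atleast_2d(value(e_i)) if not isinstance(e_i, Tensor) else e_i
    e_j2 = np.atleast_2d(value(e_j)) if not isinstance(e_j, Tensor) else e_j
    z = F.bilinear_logits(e_i2, W_cls, e_j2)
    p = F.softmax(z)
    return value(p)[0] if not isinstance(p, Tensor) else p


def document_loss(pair_probabilities, gold_labels) -> float:
    """Summed negative log-likelihood −Σ log p(r = r*) over candidate pairs
    (probabilities clipped away from 0 for numerical safety)."""
    p = np.asarray(value(pair_probabilities), dtype=float)
    labels = np.asarray(gold_labels, dtype=np.intp)
    picked = np.clip(p[np.arange(len(labels)), labels], 1e-300, None)
    return float(-np.log(picked).sum())


def predict(model: Model, corpus: Corpus,
            caches: dict[str, DocumentCache] | None = None) -> list[ScoredRelation]:
    """Score every candidate pair of every document; a pair is predicted
    positive iff p(r=1) exceeds the decision threshold. Output is ranked
    by score (descending), ties broken by pair identity."""
    out: list[ScoredRelation] = []
    for doc in corpus:
        cache = caches.get(doc.doc_id) if caches else None
        pairs, logits = model.forward_document(doc, cache)
        if logits is None:
            continue
        probs = F.softmax(value(logits))
        for (chem, dis, _), p1 in zip(pairs, probs[:, 1]):
            out.append(ScoredRelation(
                doc.doc_id, chem, dis, float(p1),
                int(p1 > model.config.threshold),
            ))
    out.sort(key=lambda r: (-r.score, r.doc_id, r.chemical_id, r.disease_id))
    return out


def train(
    corpus_train: Corpus,
    corpus_dev: Corpus | None,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    model: Model | None = None,
    pretrained: dict[str, np.ndarray] | None = None,
) -> Model:
    """Fit a model on ``corpus_train``; deterministic given ``config.seed``.

    Per-epoch loss and monitored P/R/F1 are appended to ``model.history``.
    Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    if len(corpus_train) == 0:
        raise ValueError("training corpus is empty")
    model_config = model_config or ModelConfig()
    if model is None:
        vocab_tokens = [t for d in corpus_train for s in d.sentences for t in s]
        model = Model.init(vocab_tokens, model_config, seed=config.seed,
                           pretrained=pretrained)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7124]))
    caches = {d.doc_id: model.prepare(d) for d in corpus_train}
    monitor_corpus = corpus_dev if corpus_dev is not None and len(corpus_dev) else corpus_train
    monitor_caches = (
        caches if monitor_corpus is corpus_train
        else {d.doc_id: model.prepare(d) for d in monitor_corpus}
    )

    if config.negative_subsample is not None:
        for cache in caches.values():
            keep = [
                (c, d, y) for c, d, y in cache.pairs
                if y == 1 or rng.random() < config.negative_subsample
            ]
            cache.train_pairs = keep  # type: ignore[attr-defined]

    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum)
    docs = list(corpus_train)
    best = {"f1": -1.0, "snap": model.snapshot(), "epoch": -1}
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(docs))
        total_loss = 0.0
        n_pairs = 0
        for start in range(0, len(docs), config.batch_docs):
            batch = [docs[i] for i in order[start : start + config.batch_docs]]
            opt.zero_grad()
            losses = []
            for doc in batch:
                cache = caches[doc.doc_id]
                pairs, logits = model.forward_document(doc, cache)
                if logits is None:
                    continue
                train_pairs = getattr(cache, "train_pairs", pairs)
                if len(train_pairs) < len(pairs):
                    keep_idx = [i for i, p in enumerate(pairs) if p in set(train_pairs)]
                    logits = F.gather_rows(logits, keep_idx)
                    labels = [y for _, _, y in train_pairs]
                else:
                    labels = [y for _, _, y in pairs]
                losses.append(F.cross_entropy(logits, labels))
                n_pairs += len(labels)
            if not losses:
                continue
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            if not np.isfinite(value(loss)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={value(loss)}"
                )
            loss.backward()
            clip_gradients(model.parameters(), config.clip_norm)
            opt.step()
            total_loss += float(value(loss))

        preds = predict(model, monitor_corpus, monitor_caches)
        report = evaluate(monitor_corpus, preds)
        entry = {
            "epoch": epoch,
            "loss": total_loss,
            "mean_pair_loss": total_loss / max(n_pairs, 1),
            "monitor": "dev" if monitor_corpus is not corpus_train else "train",
            "precision": report.overall.precision,
            "recall": report.overall.recall,
            "f1": report.overall.f1,
        }
        model.history.append(entry)
        logger.info("epoch %d loss %.4f %s-F1 %.4f", epoch, total_loss,
                    entry["monitor"], entry["f1"])

        if report.overall.f1 > best["f1"]:
            best = {"f1": report.overall.f1, "snap": model.snapshot(), "epoch": epoch}
            stale = 0
        else:
            stale += 1
        if report.overall.f1 >= config.stop_f1 or stale > config.patience:
            break

    model.restore(best["snap"])
    return model
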