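"""Standard synthetic-study protocols.

These functions define the package's reference experiments on generated
corpora: end-to-end relation recovery, the aggregation-layer ablation with
its intra/inter breakdown, and the connection-mechanism depth comparison.
They are used both by the test suite and by ``scripts/acceptance.py``, so
the protocols live in one place.

Model dimensions for synthetic studies are deliberately small (24-dim
embeddings and hidden states, 8-dim node-type embeddings) — the planted
signals are low-dimensional, and small models keep the full protocol
affordable on one CPU; see docs/methods.md.
"""
from __future__ import annotations

import statistics
from dataclasses import replace

from .evaluate import EvalReport, evaluate
from .model import ModelConfig
from .synthetic import SynthConfig, generate_splits
from .train import TrainConfig, predict, train
from .types import Corpus

#: reference architecture for synthetic studies (4-layer gated stack)
SMALL_MODEL = ModelConfig(d_w=24, d_h=24, d_t=8, n_gcn_layers=4, gcn_mode="gated")

#: reference optimization settings for synthetic studies
SMALL_TRAIN = TrainConfig(lr=0.02, momentum=0.9, epochs=60, patience=12)


def _fit_and_score(
    train_c: Corpus, dev_c: Corpus, eval_c: Corpus,
    model_config: ModelConfig, train_config: TrainConfig, seed: int,
) -> tuple[EvalReport, EvalReport]:
    model = train(train_c, dev_c, replace(train_config, seed=seed),
                  model_config=model_config)
    return (
        evaluate(train_c, predict(model, train_c)),
        evaluate(eval_c, predict(model, eval_c)),
    )


def end_to_end_recovery(
    corpus_seed: int,
    train_seeds: tuple[int, ...] = (0, 1, 2),
    n_train: int = 200,
    n_dev: int = 30,
    n_test: int = 50,
) -> dict:
    """Train the full model on a default synthetic corpus (30% of positive
    pairs inter-sentence) and report median training / held-out scores over
    the training seeds."""
    splits = generate_splits(SynthConfig(seed=corpus_seed), n_train, n_dev, n_test)
    train_c, dev_c, test_c = splits
    rows = []
    for seed in train_seeds:
        rep_tr, rep_te = _fit_and_score(train_c, dev_c, test_c,
                                        SMALL_MODEL, SMALL_TRAIN, seed)
        rows.append({
            "seed": seed,
            "train_f1": rep_tr.overall.f1,
            "test_f1": rep_te.overall.f1,
            "test_precision": rep_te.overall.precision,
            "test_recall": rep_te.overall.recall,
            "test_intra_f1": rep_te.intra.f1,
            "test_inter_f1": rep_te.inter.f1,
        })
    med = lambda k: statistics.median(r[k] for r in rows)
    return {
        "per_seed": rows,
        "median_train_f1": med("train_f1"),
        "median_test_f1": med("test_f1"),
        "median_test_precision": med("test_precision"),
        "median_test_recall": med("test_recall"),
        "median_test_intra_f1": med("test_intra_f1"),
        "median_test_inter_f1": med("test_inter_f1"),
    }


def aggregation_ablation(
    corpus_seed: int,
    train_seeds: tuple[int, ...] = (0, 1, 2),
    n_train: int = 200,
    n_dev: int = 40,
    n_test: int = 40,
) -> dict:
    """Full model vs. classifier-on-encoder-only entities ("without the
    aggregation layer") on a contrast corpus: half of the positive pairs
    are inter-sentence and the decoy-document rate is raised to 0.35, so
    the anaphoric document shape alone is only weakly predictive and the
    mention-less verdict sentence carries the inter-sentence label."""
    cfg = SynthConfig(seed=corpus_seed, inter_fraction=0.5, decoy_rate=0.35)
    train_c, dev_c, test_c = generate_splits(cfg, n_train, n_dev, n_test)
    out: dict = {}
    for name, mcfg in (
        ("full", SMALL_MODEL),
        ("no_aggregation", replace(SMALL_MODEL, n_gcn_layers=0)),
    ):
        rows = []
        for seed in train_seeds:
            _, rep = _fit_and_score(train_c, dev_c, test_c, mcfg, SMALL_TRAIN, seed)
            rows.append({"seed": seed, "test_f1": rep.overall.f1,
                         "intra_f1": rep.intra.f1, "inter_f1": rep.inter.f1})
        out[name] = {
            "per_seed": rows,
            "median_inter_f1": statistics.median(r["inter_f1"] for r in rows),
            "median_intra_f1": statistics.median(r["intra_f1"] for r in rows),
            "median_f1": statistics.median(r["test_f1"] for r in rows),
        }
    return out


def depth_comparison(
    corpus_seed: int,
    train_seeds: tuple[int, ...] = (0, 1, 2),
    n_layers: int = 8,
    n_train: int = 120,
    n_dev: int = 30,
    n_test: int = 40,
) -> dict:
    """Gated vs. plain convolutions at depth ``n_layers`` (development-set
    F1, median over seeds) on a default corpus — deep plain stacks smooth
    node representations into indistinguishability while gating preserves
    them."""
    train_c, dev_c, _ = generate_splits(SynthConfig(seed=corpus_seed),
                                        n_train, n_dev, n_test)
    tcfg = replace(SMALL_TRAIN, epochs=80, patience=20)
    out: dict = {}
    for mode in ("gated", "plain"):
        mcfg = replace(SMALL_MODEL, gcn_mode=mode, n_gcn_layers=n_layers)
        f1s = []
        for seed in train_seeds:
            try:
                model = train(train_c, dev_c, replace(tcfg, seed=seed),
                              model_config=mcfg)
                rep = evaluate(dev_c, predict(model, dev_c))
                f1s.append(rep.overall.f1)
            except RuntimeError:  # divergence counts as a failed run
                f1s.append(0.0)
        out[mode] = {"dev_f1_per_seed": f1s, "median_dev_f1": statistics.median(f1s)}
    return out
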