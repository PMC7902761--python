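"""Synthetic PubTator corpora with planted chemical-induced disease relations.

The generator emulates the *structural* statistics of document-level
chemical–disease corpora — multi-sentence abstracts, multi-mention entities
normalized to MeSH-shaped concept ids, document-level relation labels, and a
configurable fraction of positive pairs realized only across sentences —
while keeping the pair label a deterministic function of lexical witness
templates, so that a sufficiently expressive model can recover the labels
exactly and every downstream stage is testable without external downloads.

Witness templates (``cue`` defaults to ``"induced"``):

* intra-sentence positive — one sentence holds both mentions and the cue::

      Chm012345 induced Dis501234 .

* inter-sentence positive — realized in *anaphoric* documents holding
  exactly one chemical and one disease, through three sentences: the
  chemical's "administered" sentence, a plain home sentence for the
  disease, and an anaphoric *verdict* sentence that carries the cue but
  **no entity mention at all**::

      Chm012345 was administered .
      Dis501234 was observed .
      The drug induced <w> <w> .

  A fraction ``decoy_rate`` of all documents are *decoy* anaphoric
  documents whose mention-bearing sentences are structurally identical but
  whose verdict sentence is replaced by plain filler of the same length,
  and whose single pair is negative. Positive and decoy anaphoric
  documents are therefore indistinguishable from the sentences containing
  entity mentions alone: the label is decidable only through the
  mention-less verdict sentence, which reaches entity representations via
  graph propagation through sentence nodes but is invisible to a
  classifier over encoder-only entity nodes;

* negatives co-occur in plain sentences without the cue::

      Chm012345 and Dis509999 were observed .

All positive pairs within one document share a single "hub" chemical, so the
label remains a deterministic function of the visible cues under the full
chemical × disease candidate cross-product (two disjoint positive pairs
would otherwise make their cross pairs carry both witness cues while being
labeled negative).

Two independent RNG streams are used — one for document structure, one for
the pseudo-word lexicon and filler — so structural counts are stable under
vocabulary changes.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .corpus_io import _group_concepts, segment_and_align, DEFAULT_CONFIG
from .evaluate import INTRA, split_intra_inter
from .types import Corpus, Document, EntityType, Mention, RelationFact


class SynthesisError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic study.

    ``inter_fraction`` (default 0.30) is the fraction of positive pairs
    realized only across sentences, and roughly 2/3 of concepts carry
    multiple mentions in different sentences, matching the structural
    statistics reported for the BioCreative V chemical–disease corpus.
    """

    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (4, 9)
    chemicals_per_doc: tuple[int, int] = (1, 3)
    diseases_per_doc: tuple[int, int] = (1, 3)
    mentions_per_concept: tuple[int, int] = (1, 3)
    inter_fraction: float = 0.30
    positive_rate: float = 0.30
    vocab_size: int = 150
    cue_token: str = "induced"
    concept_pool_size: int = 30
    decoy_rate: float = 0.2
    verdict_repeats: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("sentences_per_doc", "chemicals_per_doc",
                     "diseases_per_doc", "mentions_per_concept"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise SynthesisError(f"{name} range ({lo},{hi}) is degenerate")
        if not (0.0 <= self.inter_fraction <= 1.0):
            raise SynthesisError("inter_fraction must lie in [0,1]")
        if not (0.0 <= self.positive_rate <= 1.0):
            raise SynthesisError("positive_rate must lie in [0,1]")
        if self.vocab_size < 10:
            raise SynthesisError("vocab_size must be >= 10")
        if (
            self.inter_fraction > 0.0
            and self.positive_rate > 0.0
            and self.sentences_per_doc[1] < 3
        ):
            raise SynthesisError(
                "inter-sentence positives need at least 3 sentences per "
                f"document; sentences_per_doc={self.sentences_per_doc}"
            )
        if not (0.0 <= self.decoy_rate <= 0.8):
            raise SynthesisError("decoy_rate must lie in [0, 0.8]")
        if self.verdict_repeats < 1:
            raise SynthesisError("verdict_repeats must be >= 1")
        if (
            self.inter_fraction > 0.0
            and self.positive_rate > 0.0
            and self.sentences_per_doc[1] < 3 + self.verdict_repeats
        ):
            raise SynthesisError(
                "sentence budget cannot hold the anaphoric document shape"
            )

    def as_dict(self) -> dict:
        return asdict(self)


_RESERVED = {"was", "were", "administered", "observed", "and", "the", "drug",
              "prevented"}


def _make_vocab(rng: np.random.Generator, size: int, cue: str) -> list[str]:
    """Deterministic pseudo-word lexicon: lowercase strings, disjoint from
    the template/reserved words and the cue token."""
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    words: list[str] = []
    seen = set(_RESERVED) | {cue.lower()}
    while len(words) < size:
        n = int(rng.integers(4, 8))
        w = "".join(rng.choice(letters, size=n))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _surface(concept_id: str, etype: EntityType) -> str:
    stem = "Chm" if etype == EntityType.CHEMICAL else "Dis"
    return stem + concept_id[1:]


@dataclass
class _DocPlan:
    nc: int
    nd: int
    t_draw: int
    chems: list[str]
    diseases: list[str]
    hub: str
    pos_diseases: list[str]
    mention_targets: dict[str, int]
    anaphoric: str | None = None  # None | "positive" | "decoy"

    @property
    def n_pos(self) -> int:
        return len(self.pos_diseases)

    def required_sentences(self, verdict_repeats: int = 1) -> int:
        if self.anaphoric is not None:
            # title + admin + disease home + repeated verdict block
            return 3 + verdict_repeats
        unplaced = (self.nc - 1) + (self.nd - self.n_pos)
        homes = (unplaced + 1) // 2
        return 1 + self.n_pos + homes  # title + intra witnesses + homes

    def convert_to_anaphoric(self, kind: str) -> None:
        """Reshape into the minimal one-chemical/one-disease anaphoric
        document; positive and decoy shapes are identical by construction."""
        keep = self.pos_diseases[0] if self.pos_diseases else self.diseases[0]
        self.anaphoric = kind
        self.nc, self.nd = 1, 1
        self.chems = [self.hub]
        self.diseases = [keep]
        self.pos_diseases = [keep] if kind == "positive" else []
        self.mention_targets = {
            c: self.mention_targets[c] for c in (self.hub, keep)
        }


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate a deterministic, PubTator-valid corpus under ``config``.

    Exactly ``round(inter_fraction * n_positives)`` positive pairs are
    realized across sentences (no sentence contains mentions of both
    concepts of such a pair); the remainder are witnessed within a single
    sentence. Raises :class:`SynthesisError` if the sentence budget cannot
    accommodate the requested structure.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0x5EED])
    rs, rl = [np.random.default_rng(s) for s in ss.spawn(2)]

    vocab = _make_vocab(rl, config.vocab_size, config.cue_token)
    pool_chem = [f"D{int(i):06d}" for i in
                 rs.choice(500_000, size=config.concept_pool_size, replace=False)]
    pool_dis = [f"D{int(i) + 500_000:06d}" for i in
                rs.choice(500_000, size=config.concept_pool_size, replace=False)]

    # ---- phase 1: structural plans -----------------------------------
    plans: list[_DocPlan] = []
    for _ in range(config.n_docs):
        nc = int(rs.integers(config.chemicals_per_doc[0], config.chemicals_per_doc[1] + 1))
        nd = int(rs.integers(config.diseases_per_doc[0], config.diseases_per_doc[1] + 1))
        t_draw = int(rs.integers(config.sentences_per_doc[0], config.sentences_per_doc[1] + 1))
        chems = [pool_chem[i] for i in rs.choice(len(pool_chem), size=nc, replace=False)]
        diseases = [pool_dis[i] for i in rs.choice(len(pool_dis), size=nd, replace=False)]
        n_pos = min(nd, int(round(config.positive_rate * nc * nd)))
        hub = chems[int(rs.integers(nc))]
        pos_diseases = [diseases[i] for i in rs.choice(nd, size=n_pos, replace=False)]
        targets = {
            c: int(rs.integers(config.mentions_per_concept[0],
                               config.mentions_per_concept[1] + 1))
            for c in chems + diseases
        }
        plans.append(_DocPlan(nc, nd, t_draw, chems, diseases, hub,
                              pos_diseases, targets))

    # ---- phase 2: exact global intra/inter split ---------------------
    # An inter-sentence positive occupies a whole anaphoric document.
    # Converting a document with k intra positives into an anaphoric one
    # changes the total positive count P by 1 − k, so the number of
    # conversions m must satisfy the fixed point m == round(f · P(m)).
    # Greedy selection: documents with exactly one planned positive leave
    # the target unchanged (unit progress), zero-positive documents raise
    # it by at most one, multi-positive documents are used only while the
    # remaining gap absorbs their jump.
    t_hi = config.sentences_per_doc[1]
    f = config.inter_fraction
    order = [
        int(d) for d in rs.permutation(len(plans))
        if t_hi >= 3 + config.verdict_repeats
    ]

    # decoy anaphoric documents first: a fixed fraction of the corpus,
    # converted before positive selection so their planned positives never
    # enter the count
    n_decoys = int(round(config.decoy_rate * len(plans)))
    if n_decoys > len(order):
        raise SynthesisError("sentence budget too small for anaphoric documents")
    for d in order[:n_decoys]:
        plans[d].convert_to_anaphoric("decoy")
    order = order[n_decoys:]

    by_k: dict[int, list[int]] = {}
    for d in order:
        by_k.setdefault(plans[d].n_pos, []).append(d)

    def target(p: int) -> int:
        # round half UP so the target is monotone in p (banker's rounding
        # would make it jump at f = 0.5)
        return int(np.floor(f * p + 0.5))

    p_total = sum(plan.n_pos for plan in plans)
    m = 0
    while m != target(p_total):
        gap = target(p_total) - m
        pick = None
        # single-positive documents first (unit progress, composition kept
        # rich in anaphoric positives), then zero-positive ones, then
        # multi-positive documents under an exact no-overshoot guard
        for k in [1, 0] + sorted(k for k in by_k if k >= 2):
            if not by_k.get(k):
                continue
            if 0 <= target(p_total + 1 - k) - (m + 1) <= gap:
                pick = by_k[k].pop(0)
                break
        if pick is not None:
            p_total += 1 - plans[pick].n_pos
            plans[pick].convert_to_anaphoric("positive")
            m += 1
            continue
        # endgame lever: drop one planned intra positive from the richest
        # remaining document, then retry (always reduces the target gap)
        demotable = max((k for k in by_k if k >= 2 and by_k[k]), default=None)
        if demotable is None:
            raise SynthesisError(
                "could not realize the requested inter_fraction; lower "
                "inter_fraction or positive_rate, or add documents"
            )
        d = by_k[demotable].pop(0)
        plans[d].pos_diseases = plans[d].pos_diseases[:-1]
        by_k.setdefault(demotable - 1, []).append(d)
        p_total -= 1
    n_inter_total = m

    for d, plan in enumerate(plans):
        if plan.required_sentences(config.verdict_repeats) > t_hi:
            raise SynthesisError(
                f"document plan {d} needs "
                f"{plan.required_sentences(config.verdict_repeats)} "
                f"sentences but the budget is {t_hi}"
            )

    # ---- phase 3: realization ----------------------------------------
    documents = [
        _realize(plan, f"{90_000_000 + i}", config, rs, rl, vocab)
        for i, plan in enumerate(plans)
    ]
    corpus = Corpus(documents=documents, split_tag="synthetic")
    _check_witnesses(corpus)
    stats = corpus_stats(corpus)
    if stats["inter_positives"] != n_inter_total:
        raise AssertionError(
            "generator bug: realized inter count "
            f"{stats['inter_positives']} != planned {n_inter_total}"
        )
    return corpus


def _filler(rl: np.random.Generator, vocab: list[str], n: int) -> list[str]:
    return [vocab[int(i)] for i in rl.integers(0, len(vocab), size=n)]


def _realize(
    plan: _DocPlan,
    doc_id: str,
    config: SynthConfig,
    rs: np.random.Generator,
    rl: np.random.Generator,
    vocab: list[str],
) -> Document:
    etype_of = {c: EntityType.CHEMICAL for c in plan.chems}
    etype_of.update({d: EntityType.DISEASE for d in plan.diseases})
    cue = config.cue_token

    sentences: list[list[str]] = []
    placements: list[list[tuple[int, str]]] = []  # per sentence: (token_idx, concept)

    def add(tokens: list[str], marks: list[tuple[int, str]]) -> None:
        sentences.append(tokens)
        placements.append(marks)

    # title (always the first sentence, filler only)
    title_words = _filler(rl, vocab, int(rs.integers(3, 6)))
    title_words[0] = title_words[0].capitalize()
    add(title_words, [])

    if plan.anaphoric is not None:
        # chemical marker sentence, a plain home for the disease, and a
        # mention-less anaphoric verdict; decoys carry equal-length filler
        # in place of the verdict, so only that sentence separates them
        add([_surface(plan.hub, EntityType.CHEMICAL), "was", "administered", "."],
            [(0, plan.hub)])
        add([_surface(plan.diseases[0], EntityType.DISEASE), "was", "observed", "."],
            [(0, plan.diseases[0])])
        for _ in range(config.verdict_repeats):
            if plan.anaphoric == "positive":
                add(["The", "drug", cue, *_filler(rl, vocab, 2), "."], [])
            else:
                words = _filler(rl, vocab, 5)
                words[0] = words[0].capitalize()
                add(words + ["."], [])
    else:
        for dis in plan.pos_diseases:
            add([_surface(plan.hub, EntityType.CHEMICAL), cue,
                 _surface(dis, EntityType.DISEASE), "."],
                [(0, plan.hub), (2, dis)])

    # homes for concepts not yet mentioned; chemical–disease pairs first so
    # negatives co-occur (without the cue), then leftovers
    placed = {c for marks in placements for _, c in marks}
    free_chems = [c for c in plan.chems if c not in placed]
    free_dis = [d for d in plan.diseases if d not in placed]
    while free_chems and free_dis:
        a, b = free_chems.pop(0), free_dis.pop(0)
        add([_surface(a, etype_of[a]), "and", _surface(b, etype_of[b]),
             "were", "observed", "."],
            [(0, a), (2, b)])
    leftovers = free_chems + free_dis
    while len(leftovers) >= 2:
        a, b = leftovers.pop(0), leftovers.pop(0)
        add([_surface(a, etype_of[a]), "and", _surface(b, etype_of[b]),
             "were", "observed", "."],
            [(0, a), (2, b)])
    for a in leftovers:
        add([_surface(a, etype_of[a]), "was", "observed", "."], [(0, a)])

    # extra mentions (one per sentence, so inter-pair separation is never
    # violated), then pure filler, up to the sentence budget
    counts = {c: 0 for c in etype_of}
    for marks in placements:
        for _, c in marks:
            counts[c] += 1
    extras = [c for c in plan.chems + plan.diseases
              for _ in range(max(0, plan.mention_targets[c] - counts[c]))]
    extras.sort(key=lambda c: counts[c])  # concepts in one sentence first

    t_lo, t_hi = config.sentences_per_doc
    if plan.anaphoric is not None:
        # anaphoric documents stay minimal (identically for positives and
        # decoys): witness structure plus extra-mention sentences only
        t_actual = min(t_hi, len(sentences) + len(extras))
    else:
        t_actual = max(plan.t_draw, min(t_hi, len(sentences) + len(extras)))
    for c in extras:
        if len(sentences) >= t_actual:
            break
        words = _filler(rl, vocab, 2)
        add([_surface(c, etype_of[c]), *words, "."], [(0, c)])
    while len(sentences) < t_actual:
        words = _filler(rl, vocab, int(rs.integers(3, 6)))
        words[0] = words[0].capitalize()
        add(words + ["."], [])

    # shuffle everything but the title
    order = [0] + [1 + int(i) for i in rs.permutation(len(sentences) - 1)]
    sentences = [sentences[i] for i in order]
    placements = [placements[i] for i in order]

    # ---- assemble text and character offsets -------------------------
    title = " ".join(sentences[0])
    abstract = " ".join(" ".join(toks) for toks in sentences[1:])
    text = title + "\n" + abstract

    offsets: list[list[int]] = []  # per sentence: char offset of each token
    pos = 0
    for si, toks in enumerate(sentences):
        row = []
        for ti, tok in enumerate(toks):
            row.append(pos)
            pos += len(tok) + 1  # single space / separator after each token
        offsets.append(row)

    mentions: list[Mention] = []
    for si, marks in enumerate(placements):
        for ti, concept in marks:
            start = offsets[si][ti]
            surf = sentences[si][ti]
            mentions.append(Mention(
                doc_id=doc_id, char_start=start, char_end=start + len(surf),
                surface=surf, etype=etype_of[concept], concept_id=concept,
            ))
    mentions.sort(key=lambda m: (m.char_start, m.concept_id))
    for m in mentions:
        if text[m.char_start:m.char_end] != m.surface:
            raise AssertionError(
                f"generator offset bug in {doc_id}: {m.surface!r} vs "
                f"{text[m.char_start:m.char_end]!r}"
            )

    relations = [RelationFact(doc_id, plan.hub, d, 1) for d in plan.pos_diseases]
    doc = Document(
        doc_id=doc_id, title=title, abstract=abstract,
        mentions=mentions, concepts=_group_concepts(doc_id, mentions),
        gold_relations=relations,
    )
    segment_and_align(doc, DEFAULT_CONFIG)
    doc.validate()
    return doc


def _check_witnesses(corpus: Corpus) -> None:
    """Post-generation self-check: planted intra/inter status must agree
    with the evaluation module's splitter."""
    for doc in corpus:
        for r in doc.gold_relations:
            kind = split_intra_inter(doc, (r.chemical_id, r.disease_id))
            chem_sents = doc.sentences_of_concept(r.chemical_id)
            dis_sents = doc.sentences_of_concept(r.disease_id)
            if kind == INTRA and not (chem_sents & dis_sents):
                raise AssertionError("intra witness lost during realization")


def generate_splits(
    config: SynthConfig, n_train: int, n_dev: int, n_test: int
) -> tuple[Corpus, Corpus, Corpus]:
    """One generation run sliced into train/dev/test corpora that share the
    concept pool and lexicon (so held-out evaluation tests generalization
    over contexts, not vocabulary mismatch)."""
    from dataclasses import replace

    total = n_train + n_dev + n_test
    corpus = generate_corpus(replace(config, n_docs=total))
    docs = corpus.documents
    mk = lambda ds, tag: Corpus(documents=ds, split_tag=tag)
    return (
        mk(docs[:n_train], "train"),
        mk(docs[n_train:n_train + n_dev], "dev"),
        mk(docs[n_train + n_dev:], "test"),
    )


def corpus_stats(corpus: Corpus) -> dict:
    """Exact structural counts of a corpus (any corpus, not only synthetic)."""
    n_sent = sum(d.n_sentences for d in corpus)
    n_men = sum(len(d.mentions) for d in corpus)
    n_con = sum(len(d.concepts) for d in corpus)
    n_pairs = 0
    positives = intra = inter = 0
    multi = 0
    for doc in corpus:
        from .corpus_io import enumerate_candidate_pairs

        pairs = enumerate_candidate_pairs(doc)
        n_pairs += len(pairs)
        for chem, dis, label in pairs:
            if label == 1:
                positives += 1
                if split_intra_inter(doc, (chem, dis)) == INTRA:
                    intra += 1
                else:
                    inter += 1
        for c in doc.concepts:
            sents = {doc.mentions[i].sentence_index for i in c.mention_indices}
            if len(sents) >= 2:
                multi += 1
    return {
        "documents": len(corpus),
        "sentences": n_sent,
        "mentions": n_men,
        "concepts": n_con,
        "candidate_pairs": n_pairs,
        "positives": positives,
        "intra_positives": intra,
        "inter_positives": inter,
        "multi_mention_entity_fraction": (multi / n_con) if n_con else 0.0,
    }
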