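"""The full relation-extraction model: embeddings → BiLSTM → document graph
→ stacked (gated) graph convolutions → bilinear pair classifier.

For each document, every chemical × disease concept pair is scored with a
bilinear form over the final entity-node representations,
``z_r = e_chemᵀ W_cls[r] e_dis`` for the two labels r ∈ {0, 1}, followed by
a softmax. The chemical is always the left argument (the bilinear form is
order-sensitive).
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autodiff as F
from ._autodiff import Tensor, value
from .corpus_io import enumerate_candidate_pairs
from .encoder import (
    EmbeddingTable,
    LstmParams,
    NodeTypeEmbeddings,
    bilstm_encode_batch,
    build_nodes_flat,
)
from .gcn import DenseProjection, GcnConfig, GcnLayerParams, forward as gcn_forward
from .graph import build_adjacency, make_fully_connected, normalize_adjacency
from .types import Document

K_LABELS = 2


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration for real corpora
    (300-dim word embeddings, 300 one-side LSTM hidden units, 50-dim
    node-type embeddings, 4 gated graph-convolution layers); synthetic
    experiments use smaller dimensions set explicitly.
    """

    d_w: int = 300
    d_h: int = 300
    d_t: int = 50
    n_gcn_layers: int = 4
    gcn_mode: str = "gated"
    negative_slope: float = 0.01
    adjacency_mode: str = "none"
    fully_connected: bool = False
    freeze_embeddings: bool = False
    threshold: float = 0.5

    @property
    def d_node(self) -> int:
        return self.d_h + self.d_t

    def gcn_config(self) -> GcnConfig:
        return GcnConfig(
            n_layers=self.n_gcn_layers,
            mode=self.gcn_mode,
            negative_slope=self.negative_slope,
            adjacency_mode=self.adjacency_mode,
        )


@dataclass
class DocumentCache:
    """Static per-document tensors reused across epochs."""

    index_lists: list[np.ndarray]
    A: np.ndarray
    pairs: list[tuple[str, str, int]]


class Model:
    """All trainable parameter containers plus the forward pass."""

    def __init__(
        self,
        config: ModelConfig,
        embeddings: EmbeddingTable,
        lstm_fwd: LstmParams,
        lstm_bwd: LstmParams,
        type_embeddings: NodeTypeEmbeddings,
        gcn_layers: list[GcnLayerParams],
        W_cls: Tensor,
        dense_projection: DenseProjection | None = None,
    ):
        self.config = config
        self.embeddings = embeddings
        self.lstm_fwd = lstm_fwd
        self.lstm_bwd = lstm_bwd
        self.type_embeddings = type_embeddings
        self.gcn_layers = gcn_layers
        self.W_cls = W_cls
        self.dense_projection = dense_projection
        self.history: list[dict] = []

    # -- construction ---------------------------------------------------
    @classmethod
    def init(
        cls,
        vocab_tokens: Sequence[str],
        config: ModelConfig,
        seed: int = 0,
        pretrained: dict[str, np.ndarray] | None = None,
    ) -> "Model":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1D]))
        emb = EmbeddingTable.build(
            vocab_tokens, config.d_w, rng,
            trainable=not config.freeze_embeddings, pretrained=pretrained,
        )
        d = config.d_node
        gated = config.gcn_mode == "gated"
        layers = [
            GcnLayerParams.init(d, rng, gated=gated)
            for _ in range(config.n_gcn_layers)
        ]
        dense = (
            DenseProjection.init(d, config.n_gcn_layers, rng)
            if config.gcn_mode == "dense" and config.n_gcn_layers > 0
            else None
        )
        return cls(
            config=config,
            embeddings=emb,
            lstm_fwd=LstmParams.init(config.d_w, config.d_h, rng),
            lstm_bwd=LstmParams.init(config.d_w, config.d_h, rng),
            type_embeddings=NodeTypeEmbeddings.init(config.d_t, rng),
            gcn_layers=layers,
            W_cls=F.parameter(rng, (K_LABELS, d, d), fan_in=d * d),
            dense_projection=dense,
        )

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.embeddings.trainable:
            out.append(self.embeddings.matrix)
        out += self.lstm_fwd.parameters() + self.lstm_bwd.parameters()
        out += self.type_embeddings.parameters()
        for layer in self.gcn_layers:
            out += layer.parameters()
        if self.dense_projection is not None:
            out += self.dense_projection.parameters()
        out.append(self.W_cls)
        return out

    # -- forward --------------------------------------------------------
    def prepare(self, doc: Document) -> DocumentCache:
        index_lists = [self.embeddings.indices(s) for s in doc.sentences]
        graph = build_adjacency(doc)
        if self.config.fully_connected:
            graph = make_fully_connected(graph)
        A = normalize_adjacency(graph.A, self.config.adjacency_mode)
        return DocumentCache(index_lists, A, enumerate_candidate_pairs(doc))

    def forward_document(self, doc: Document, cache: DocumentCache | None = None):
        """Score all candidate pairs of one document.

        Returns ``(pairs, logits)`` where ``pairs`` is the deterministic
        candidate list and ``logits`` the (p, 2) bilinear scores (``None``
        when the document has no chemical or no disease concept).
        """
        cache = cache or self.prepare(doc)
        if not cache.pairs:
            return [], None
        H_all, offsets = bilstm_encode_batch(
            cache.index_lists, self.embeddings.matrix, self.lstm_fwd, self.lstm_bwd
        )
        nodes = build_nodes_flat(doc, H_all, offsets, self.type_embeddings)
        V = gcn_forward(
            nodes.V, cache.A, self.gcn_layers, self.config.gcn_config(),
            dense_projection=self.dense_projection,
        )
        chem_rows = [nodes.entity_rows[c] for c, _, _ in cache.pairs]
        dis_rows = [nodes.entity_rows[d] for _, d, _ in cache.pairs]
        E_chem = F.gather_rows(V, chem_rows)
        E_dis = F.gather_rows(V, dis_rows)
        logits = F.bilinear_logits(E_chem, self.W_cls, E_dis)
        return cache.pairs, logits

    # -- serialization --------------------------------------------------
    def _named_parameters(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {"emb.matrix": self.embeddings.matrix}
        for tag, p in (("lstm_fwd", self.lstm_fwd), ("lstm_bwd", self.lstm_bwd)):
            for n in ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f",
                      "W_o", "U_o", "b_o", "W_c", "U_c", "b_c"):
                named[f"{tag}.{n}"] = getattr(p, n)
        for n in ("t_m", "t_e", "t_s"):
            named[f"types.{n}"] = getattr(self.type_embeddings, n)
        for i, layer in enumerate(self.gcn_layers):
            named[f"gcn{i}.W"] = layer.W
            for n in ("W_g", "U_g", "b_g"):
                q = getattr(layer, n)
                if q is not None:
                    named[f"gcn{i}.{n}"] = q
        if self.dense_projection is not None:
            named["dense.W"] = self.dense_projection.W
            named["dense.b"] = self.dense_projection.b
        named["W_cls"] = self.W_cls
        return named

    def save(self, path: str | Path) -> None:
        """Parameter archive + config snapshot + vocabulary in one file."""
        named = self._named_parameters()
        meta = json.dumps({
            "config": asdict(self.config),
            "vocab": self.embeddings.vocab,
            "d_w": self.embeddings.d_w,
            "params": list(named.keys()),
        })
        arrays = {k.replace(".", "__"): value(v) for k, v in named.items()}
        np.savez_compressed(str(path), __meta__=np.frombuffer(
            meta.encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        config = ModelConfig(**meta["config"])
        model = cls.init(["placeholder"], config, seed=0)
        emb = EmbeddingTable(
            meta["vocab"],
            Tensor(arrays["emb__matrix"], requires_grad=not config.freeze_embeddings),
            meta["d_w"],
        )
        model.embeddings = emb
        named = model._named_parameters()
        for k in meta["params"]:
            named[k].data = arrays[k.replace(".", "__")].copy()
        return model

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: value(v).copy() for k, v in self._named_parameters().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        named = self._named_parameters()
        for k, arr in snap.items():
            named[k].data = arr.copy()
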