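"""Stacked graph convolutions with four inter-layer connection mechanisms.

The basic layer is ``V' = δ(A V W)`` with a LeakyReLU activation — each
node's update is the activated, filter-transformed sum of its (self-looped)
neighborhood. Repeated application performs Laplacian-style smoothing and
eventually drives node representations toward a low-information subspace
(*over-smoothing*). Four ways of wiring consecutive layers are provided:

* ``plain``    — V_{l+1} = δ(A V_l W_l)
* ``residual`` — V_{l+1} = δ(A V_l W_l) + V_l
* ``dense``    — all layer outputs are concatenated and projected back to
  d with a learned linear map, so the classifier stays dimension-agnostic
* ``gated``    — a sigmoid gate interpolates element-wise between the
  convolved update and the previous representation,
  ``g = σ(V_raw W_g + V_l U_g + b_g)``, ``V_{l+1} = V_raw⊙g + V_l⊙(1−g)``,
  letting each coordinate keep node-specific information across layers.

Everything runs on plain arrays or autodiff tensors alike.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _autodiff as F
from ._autodiff import Tensor, value

MODES = ("plain", "residual", "dense", "gated")


@dataclass
class GcnLayerParams:
    """Per-layer parameters: the d×d convolution filter and, in gated mode,
    the gate maps W_g, U_g and bias b_g."""

    W: object
    W_g: object = None
    U_g: object = None
    b_g: object = None

    @classmethod
    def init(cls, d: int, rng: np.random.Generator, gated: bool = True) -> "GcnLayerParams":
        p = cls(W=F.parameter(rng, (d, d), fan_in=d))
        if gated:
            p.W_g = F.parameter(rng, (d, d), fan_in=d)
            p.U_g = F.parameter(rng, (d, d), fan_in=d)
            p.b_g = F.zeros_parameter((d,))  # gate starts balanced (≈0.5)
        return p

    def parameters(self) -> list[Tensor]:
        out = [self.W]
        for extra in (self.W_g, self.U_g, self.b_g):
            if isinstance(extra, Tensor):
                out.append(extra)
        return out


@dataclass
class GcnConfig:
    n_layers: int = 4
    mode: str = "gated"
    negative_slope: float = 0.01
    adjacency_mode: str = "none"  # none | sym | row

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown GCN mode {self.mode!r}")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")


def gcn_layer(V, A, W, activation=None, negative_slope: float = 0.01):
    """One graph convolution ``δ(A V W)``.

    Row i of the result equals ``δ(Σ_j a_ij V_j W)`` — the per-node
    neighborhood sum with a shared filter.
    """
    n, d = value(V).shape
    if value(A).shape != (n, n):
        raise ValueError(f"adjacency {value(A).shape} does not match {n} nodes")
    if value(W).shape[0] != d:
        raise ValueError("filter W does not match node dimension")
    pre = F.matmul(F.matmul(A, V), W)
    if activation is None:
        return F.leaky_relu(pre, negative_slope)
    return activation(pre)


def gated_update(V_raw, V_prev, W_g, U_g, b_g):
    """Element-wise sigmoid interpolation between the convolved update and
    the previous layer; every output coordinate lies between the two."""
    if value(V_raw).shape != value(V_prev).shape:
        raise ValueError("gated_update inputs must have identical shapes")
    g = F.sigmoid(F.matmul(V_raw, W_g) + F.matmul(V_prev, U_g) + b_g)
    return V_raw * g + V_prev * (1.0 - g)


@dataclass
class DenseProjection:
    """Learned (L+1)·d → d map applied to the concatenation of all layer
    outputs in dense mode, restoring the classifier's input dimension."""

    W: object
    b: object

    @classmethod
    def init(cls, d: int, n_layers: int, rng: np.random.Generator) -> "DenseProjection":
        return cls(
            W=F.parameter(rng, ((n_layers + 1) * d, d), fan_in=(n_layers + 1) * d),
            b=F.zeros_parameter((d,)),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def forward(V0, A, layers: Sequence[GcnLayerParams], config: GcnConfig,
            dense_projection: DenseProjection | None = None,
            activation=None):
    """Run the full stack; output is (n, d) in every mode.

    ``activation`` overrides the default LeakyReLU (used by diagnostics in
    the linear limit).
    """
    if len(layers) < config.n_layers:
        raise ValueError(
            f"{config.n_layers} layers configured but only "
            f"{len(layers)} parameter sets given"
        )
    act = activation if activation is not None else (
        lambda x: F.leaky_relu(x, config.negative_slope)
    )
    V = V0
    collected = [V0]
    for l in range(config.n_layers):
        p = layers[l]
        raw = gcn_layer(V, A, p.W, activation=act)
        if config.mode == "plain":
            V = raw
        elif config.mode == "residual":
            V = raw + V
        elif config.mode == "dense":
            V = raw
            collected.append(V)
        elif config.mode == "gated":
            if p.W_g is None:
                raise ValueError("gated mode requires gate parameters")
            V = gated_update(raw, V, p.W_g, p.U_g, p.b_g)
    if config.mode == "dense" and config.n_layers > 0:
        if dense_projection is None:
            raise ValueError("dense mode requires a projection back to d")
        V = F.matmul(F.concat(collected, axis=1), dense_projection.W) + dense_projection.b
    return V


def random_connected_adjacency(
    n: int, rng: np.random.Generator, edge_prob: float = 0.3
) -> np.ndarray:
    """Random symmetric self-looped adjacency, made connected by a chain."""
    A = (rng.random((n, n)) < edge_prob).astype(float)
    A = np.maximum(A, A.T)
    for i in range(n - 1):  # spanning chain guarantees connectivity
        A[i, i + 1] = A[i + 1, i] = 1.0
    np.fill_diagonal(A, 1.0)
    return A


def oversmoothing_profile(
    A: np.ndarray,
    V0: np.ndarray,
    depth: int,
    mode: str = "plain",
    gate_bias: float = 0.0,
) -> list[float]:
    """Depth-wise over-smoothing diagnostic in the linear limit.

    Repeatedly applies the convolution with identity filter and identity
    activation (so the update is pure neighborhood averaging when ``A`` is
    row-normalized); in gated mode the gate has zero weight matrices and a
    constant bias, i.e. a fixed interpolation toward the smoothed update.
    Returns the mean pairwise cosine similarity after each layer.
    """
    n, d = V0.shape
    W = np.eye(d)
    zeros = np.zeros((d, d))
    bias = np.full(d, gate_bias)
    V = V0
    out = []
    for _ in range(depth):
        raw = gcn_layer(V, A, W, activation=lambda x: x)
        if mode == "plain":
            V = raw
        elif mode == "gated":
            V = gated_update(raw, V, zeros, zeros, bias)
        else:
            raise ValueError(f"profile supports plain|gated, not {mode!r}")
        out.append(oversmoothing_metric(V))
    return out


def oversmoothing_metric(V) -> float:
    """Mean pairwise cosine similarity of node rows — 1.0 iff all rows are
    parallel (fully smoothed), 0.0 for mutually orthogonal rows."""
    X = np.asarray(value(V), dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two nodes")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm node representation")
    U = X / norms[:, None]
    C = U @ U.T
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(C[iu].mean())
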