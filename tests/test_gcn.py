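"""Graph convolutions: brute-force neighborhood oracle, gating behavior,
connection mechanisms, permutation equivariance and over-smoothing."""
from __future__ import annotations

import numpy as np
import pytest

from cidrel import _autodiff as F
from cidrel.gcn import (
    DenseProjection,
    GcnConfig,
    GcnLayerParams,
    forward,
    gated_update,
    gcn_layer,
    oversmoothing_metric,
    oversmoothing_profile,
    random_connected_adjacency,
)
from cidrel.graph import normalize_adjacency


def leaky(x, s=0.01):
    return np.where(x > 0, x, s * x)


def brute_force_layer(V, A, W, s=0.01):
    """Per-node neighborhood sum, written as an explicit loop."""
    n, d = V.shape
    out = np.zeros_like(V)
    for i in range(n):
        acc = np.zeros(d)
        for j in range(n):
            acc += A[i, j] * (V[j] @ W)
        out[i] = leaky(acc, s)
    return out


def test_eq3_style_neighbor_sum():
    # node 5 with neighbors {3, 4} plus its self-loop: the update is the
    # activated sum of exactly those three filtered rows
    rng = np.random.default_rng(0)
    n, d = 6, 3
    A = np.eye(n)
    A[5, 3] = A[3, 5] = 1
    A[5, 4] = A[4, 5] = 1
    V = rng.normal(size=(n, d))
    W = rng.normal(size=(d, d))
    out = gcn_layer(V, A, W)
    expected_row5 = leaky(V[3] @ W + V[4] @ W + V[5] @ W)
    assert np.allclose(out[5], expected_row5, atol=1e-12)


def test_layer_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = int(rng.integers(2, 21))
        d = int(rng.integers(1, 9))
        A = random_connected_adjacency(n, rng, edge_prob=float(rng.random()))
        V = rng.normal(size=(n, d))
        W = rng.normal(size=(d, d))
        assert np.max(np.abs(gcn_layer(V, A, W) - brute_force_layer(V, A, W))) < 1e-8


def test_zero_filter_gives_zero():
    rng = np.random.default_rng(2)
    V = rng.normal(size=(5, 4))
    A = random_connected_adjacency(5, rng)
    assert np.allclose(gcn_layer(V, A, np.zeros((4, 4))), 0)


def test_shape_mismatch_errors():
    with pytest.raises(ValueError):
        gcn_layer(np.zeros((3, 2)), np.zeros((4, 4)), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        gated_update(np.zeros((3, 2)), np.zeros((2, 2)),
                     np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))


class TestGatedUpdate:
    rng = np.random.default_rng(3)

    def test_equal_inputs_fixed_point(self):
        V = self.rng.normal(size=(4, 3))
        Wg, Ug = self.rng.normal(size=(3, 3)), self.rng.normal(size=(3, 3))
        out = gated_update(V, V, Wg, Ug, self.rng.normal(size=3))
        assert np.allclose(out, V, atol=1e-12)

    def test_zero_gate_parameters_give_midpoint(self):
        Vr = self.rng.normal(size=(5, 2))
        Vp = self.rng.normal(size=(5, 2))
        out = gated_update(Vr, Vp, np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        assert np.allclose(out, (Vr + Vp) / 2, atol=1e-14)

    @pytest.mark.parametrize("bias,target", [(20.0, "raw"), (-20.0, "prev")])
    def test_saturated_gate_selects_endpoint(self, bias, target):
        Vr = self.rng.normal(size=(6, 3))
        Vp = self.rng.normal(size=(6, 3))
        out = gated_update(Vr, Vp, np.zeros((3, 3)), np.zeros((3, 3)),
                           np.full(3, bias))
        expected = Vr if target == "raw" else Vp
        assert np.max(np.abs(out - expected)) < 1e-6

    def test_output_between_endpoints(self):
        Vr = self.rng.normal(size=(7, 4))
        Vp = self.rng.normal(size=(7, 4))
        out = gated_update(Vr, Vp, self.rng.normal(size=(4, 4)),
                           self.rng.normal(size=(4, 4)), self.rng.normal(size=4))
        lo, hi = np.minimum(Vr, Vp), np.maximum(Vr, Vp)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestForward:
    rng = np.random.default_rng(4)

    def _setup(self, d=3, n=4, n_layers=4, gated=True):
        A = random_connected_adjacency(n, self.rng)
        V0 = self.rng.normal(size=(n, d))
        layers = [GcnLayerParams.init(d, self.rng, gated=gated)
                  for _ in range(n_layers)]
        return V0, A, layers

    def test_single_gated_layer_is_composition(self):
        V0, A, layers = self._setup(n_layers=1)
        cfg = GcnConfig(n_layers=1, mode="gated")
        out = forward(V0, A, layers, cfg)
        p = layers[0]
        raw = gcn_layer(V0, A, F.value(p.W))
        expected = gated_update(raw, V0, F.value(p.W_g), F.value(p.U_g),
                                F.value(p.b_g))
        assert np.allclose(F.value(out), expected, atol=1e-12)

    def test_residual_with_zero_filters_is_identity(self):
        V0, A, layers = self._setup(gated=False)
        for p in layers:
            p.W = np.zeros((3, 3))
        out = forward(V0, A, layers, GcnConfig(n_layers=4, mode="residual"))
        assert np.allclose(F.value(out), V0)

    def test_plain_four_layers_vs_unrolled(self):
        V0, A, layers = self._setup(gated=False)
        out = forward(V0, A, layers, GcnConfig(n_layers=4, mode="plain"))
        V = V0
        for p in layers:
            V = brute_force_layer(V, A, F.value(p.W))
        assert np.max(np.abs(F.value(out) - V)) < 1e-8

    def test_dense_mode_projects_back_to_d(self):
        V0, A, layers = self._setup(gated=False, n_layers=2)
        proj = DenseProjection.init(3, 2, self.rng)
        out = forward(V0, A, layers, GcnConfig(n_layers=2, mode="dense"),
                      dense_projection=proj)
        assert F.value(out).shape == V0.shape
        with pytest.raises(ValueError):
            forward(V0, A, layers, GcnConfig(n_layers=2, mode="dense"))

    def test_insufficient_layers_error(self):
        V0, A, layers = self._setup(n_layers=2)
        with pytest.raises(ValueError):
            forward(V0, A, layers, GcnConfig(n_layers=3, mode="gated"))

    def test_permutation_equivariance(self):
        V0, A, layers = self._setup(n=6)
        cfg = GcnConfig(n_layers=4, mode="gated")
        out = F.value(forward(V0, A, layers, cfg))
        perm = self.rng.permutation(6)
        out_p = F.value(forward(V0[perm], A[np.ix_(perm, perm)], layers, cfg))
        assert np.allclose(out_p, out[perm], atol=1e-10)


def test_oversmoothing_metric_values():
    assert oversmoothing_metric(np.array([[1.0, 2.0], [2.0, 4.0], [0.5, 1.0]])) == pytest.approx(1.0)
    assert oversmoothing_metric(np.array([[1.0, 0.0], [0.0, 3.0]])) == pytest.approx(0.0)
    rows = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    cos = [1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)]  # pairs (0,1), (0,2), (1,2)
    assert oversmoothing_metric(rows) == pytest.approx(np.mean(cos))
    with pytest.raises(ValueError):
        oversmoothing_metric(np.array([[1.0, 0.0]]))
    with pytest.raises(ValueError):
        oversmoothing_metric(np.array([[1.0, 0.0], [0.0, 0.0]]))


def test_oversmoothing_depth_contrast():
    """Deep plain convolutions collapse all nodes onto one ray; the gate
    with a strongly negative bias preserves the initial geometry."""
    rng = np.random.default_rng(5)
    A = normalize_adjacency(random_connected_adjacency(10, rng), "row")
    V0 = rng.standard_normal((10, 6))
    init = oversmoothing_metric(V0)
    plain = oversmoothing_profile(A, V0, 64, mode="plain")
    gated = oversmoothing_profile(A, V0, 64, mode="gated", gate_bias=-10.0)
    assert plain[-1] >= 0.999
    assert abs(gated[-1] - init) < 1e-3
    assert plain == sorted(plain)  # smoothing is monotone here
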