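"""Demonstrate over-smoothing and how the gate prevents it.

In the linear limit (row-normalized adjacency, identity filter and
activation) each plain convolution is a neighborhood-averaging step; on a
connected graph, repeated averaging drives all node representations onto
one ray, so their mean pairwise cosine similarity approaches 1 and the
nodes become indistinguishable. A sigmoid gate biased toward keeping the
previous representation preserves the geometry at the same depth.
"""
import numpy as np

from cidrel.gcn import oversmoothing_metric, oversmoothing_profile, random_connected_adjacency
from cidrel.graph import normalize_adjacency

rng = np.random.default_rng(0)
A = normalize_adjacency(random_connected_adjacency(10, rng), "row")
V0 = rng.standard_normal((10, 8))

plain = oversmoothing_profile(A, V0, depth=64, mode="plain")
gated = oversmoothing_profile(A, V0, depth=64, mode="gated", gate_bias=-10.0)

print(f"initial mean pairwise cosine: {oversmoothing_metric(V0):.4f}")
print("depth   plain    gated")
for d in (1, 2, 4, 8, 16, 32, 64):
    print(f"{d:5d}  {plain[d - 1]:.4f}  {gated[d - 1]:.4f}")
# plain reaches ~1.0 (fully smoothed) well before depth 64, while the
# gated column stays at the initial value: node identity is preserved.
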