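"""The 16-node subcortical parcellation and its canonical edge indexing.

Nodes are the bilateral red nucleus (RN), substantia nigra (SN),
subthalamic nucleus (STN), caudate (CAUD), putamen (PUT), globus pallidus
externa (GPe), globus pallidus interna (GPi) and thalamus (THAL) — the
regions of the nigrostriatal pathway most affected in Parkinson's disease.

The node order is fixed (left before right within each region, regions in
the order above) so that the flattening of a connectome matrix into an
edge vector is reproducible across subjects, sessions and runs.  Edges are
the C(16, 2) = 120 unordered region pairs, enumerated row-major over the
strict upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

REGIONS = ("RN", "SN", "STN", "CAUD", "PUT", "GPe", "GPi", "THAL")
HEMISPHERES = ("L", "R")

N_NODES = 16
N_EDGES = N_NODES * (N_NODES - 1) // 2  # 120


@dataclass(frozen=True)
class AtlasNode:
    """One parcellation region with its fixed position in the node order."""

    label: str  # e.g. "L-PUT"
    index: int  # 0..15

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_NODES:
            raise ValueError(f"node index {self.index} out of range 0..15")
        hemi, _, region = self.label.partition("-")
        if hemi not in HEMISPHERES or region not in REGIONS:
            raise ValueError(f"unknown node label {self.label!r}")


#: Canonical node order: L then R within each region, regions as listed above.
ATLAS_NODES: tuple[AtlasNode, ...] = tuple(
    AtlasNode(label=f"{hemi}-{region}", index=2 * r + h)
    for r, region in enumerate(REGIONS)
    for h, hemi in enumerate(HEMISPHERES)
)

NODE_BY_LABEL: dict[str, AtlasNode] = {n.label: n for n in ATLAS_NODES}

#: Canonical edge enumeration: row-major strict upper triangle, (i, j) with i < j.
EDGE_PAIRS: tuple[tuple[AtlasNode, AtlasNode], ...] = tuple(
    (ATLAS_NODES[i], ATLAS_NODES[j])
    for i in range(N_NODES)
    for j in range(i + 1, N_NODES)
)

assert len(EDGE_PAIRS) == N_EDGES


class EdgeFeatureIndex(NamedTuple):
    """Maps one position of the 360-long feature vector to its meaning."""

    feature_index: int  # 0..359
    node_a: AtlasNode
    node_b: AtlasNode
    metric: str

    @property
    def name(self) -> str:
        return f"{self.node_a.label}__{self.node_b.label}__{self.metric}"


def edge_feature_map(metrics: tuple[str, ...] | None = None) -> list[EdgeFeatureIndex]:
    """Enumerate all 360 (region pair, metric) features in vector order.

    Feature f = 120 * m + e is edge e of metric block m, with metric blocks
    ordered streamline_count, mean_fa, mean_md.  The mapping is a bijection
    and stable across runs.
    """
    if metrics is None:
        from longconn.connectome import METRICS

        metrics = METRICS
    out: list[EdgeFeatureIndex] = []
    for m, metric in enumerate(metrics):
        for e, (a, b) in enumerate(EDGE_PAIRS):
            out.append(EdgeFeatureIndex(N_EDGES * m + e, a, b, metric))
    return out


def edge_index(node_a: str | AtlasNode, node_b: str | AtlasNode) -> int:
    """Position of the unordered pair (node_a, node_b) in the edge enumeration."""
    a = NODE_BY_LABEL[node_a].index if isinstance(node_a, str) else node_a.index
    b = NODE_BY_LABEL[node_b].index if isinstance(node_b, str) else node_b.index
    if a == b:
        raise ValueError("self-connections are not edges")
    i, j = min(a, b), max(a, b)
    # offset of row i in the strict upper triangle, then column within the row
    return i * (2 * N_NODES - i - 1) // 2 + (j - i - 1)
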