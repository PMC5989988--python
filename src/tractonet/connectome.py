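"""Dimensionless streamline-weighted connectome construction.

The edge weight between nodes i and j is

    w(e_ij) = (2 / (A_i + A_j)) * (V_voxel / P_voxel) * sum_f 1 / l(f)

where the sum runs over the streamlines connecting i and j that are
*retained* by a characteristic (indicator) filter: a streamline is retained
only if its seed voxel lies in R, the set of white-matter voxels traversed
by the edge's streamlines, excluding the member voxels of the two nodes.
A_i is the node surface area (mm^2), V_voxel the voxel volume (mm^3),
P_voxel the number of seed points per voxel and l(f) the streamline arc
length (mm), so w is dimensionless and invariant to a global rescaling of
spatial units.  Filtering out streamlines seeded inside the nodes or off
the white-matter path suppresses tractography false positives; because a
spurious connection carries few streamlines its weight is small and node
strengths are barely perturbed.

No threshold is applied anywhere: weak edges are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parcellation import NodeRegion, validate_parcellation
from .tractogram import ScalarField, Streamline, Tractogram, streamline_arclength

__all__ = [
    "Connectome",
    "EdgeOccupancy",
    "InvalidGeometryError",
    "UndefinedEdgeError",
    "segment_tractogram",
    "edge_occupancy",
    "characteristic_filter",
    "edge_weight",
    "build_connectome",
    "fa_edge_weight",
    "build_fa_connectome",
]

logger = logging.getLogger(__name__)


class InvalidGeometryError(ValueError):
    """Raised for non-physical geometry (zero areas or seed counts)."""


class UndefinedEdgeError(ValueError):
    """Raised when an edge has no white-matter voxels to average over."""


@dataclass(frozen=True)
class EdgeOccupancy:
    """White-matter voxel support of one edge.

    ``voxels`` is R: the voxels traversed by the pair's candidate
    streamlines minus both nodes' member voxels. ``streamline_refs`` are
    the indices (into the tractogram) of the retained streamlines, i.e.
    those whose seed voxel lies in R.
    """

    node_pair: tuple[int, int]
    voxels: frozenset[tuple[int, int, int]]
    streamline_refs: tuple[int, ...]

    def __post_init__(self) -> None:
        i, j = self.node_pair
        if not i < j:
            raise ValueError(f"node pair must be ordered i < j, got {self.node_pair}")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


class Connectome:
    """A symmetric, nonnegative, zero-diagonal weighted adjacency matrix
    with node metadata."""

    def __init__(
        self,
        labels: Sequence[str],
        weights: np.ndarray,
        nodes: Sequence[NodeRegion] | None = None,
    ) -> None:
        W = np.asarray(weights, dtype=float)
        n = len(labels)
        if W.shape != (n, n):
            raise ValueError(f"weight matrix {W.shape} does not match {n} labels")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(W, W.T, rtol=1e-10, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.labels = list(labels)
        self.weights = W
        self.nodes = list(nodes) if nodes is not None else None

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, Connectome)
            and self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
        )

    # ---- I/O ---------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """N x N matrix CSV with node-label header row and column."""
        df = pd.DataFrame(self.weights, index=self.labels, columns=self.labels)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Connectome":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_edgelist(self, path: str | Path) -> None:
        """TSV edge list ``node_i <TAB> node_j <TAB> weight`` (i < j, w > 0)."""
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.weights[i, j] > 0:
                    rows.append((self.labels[i], self.labels[j], self.weights[i, j]))
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_edgelist(cls, path: str | Path, labels: Sequence[str]) -> "Connectome":
        df = pd.read_csv(path, sep="\t")
        index = {lab: k for k, lab in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)))
        for _, row in df.iterrows():
            i, j = index[row["node_i"]], index[row["node_j"]]
            W[i, j] = W[j, i] = float(row["weight"])
        return cls(list(labels), W)


# ---------------------------------------------------------------------------
# streamline -> edge assignment
# ---------------------------------------------------------------------------

def _voxel_to_node_map(parcellation: Sequence[NodeRegion]) -> dict[tuple[int, int, int], int]:
    validate_parcellation(parcellation)
    mapping: dict[tuple[int, int, int], int] = {}
    for node in parcellation:
        for v in node.voxel_members:
            mapping[v] = node.node_id
    return mapping


def segment_tractogram(
    t: Tractogram, parcellation: Sequence[NodeRegion]
) -> dict[tuple[int, int], list[int]]:
    """Assign each streamline to the node pair its two endpoints terminate in.

    A streamline whose first endpoint lies in a voxel of node i and last
    endpoint in a voxel of node j (i != j) is a candidate for edge (i, j).
    Streamlines with fewer than two endpoints inside nodes, or with both
    endpoints in the same node, are dropped (counts are logged).
    """
    voxel_to_node = _voxel_to_node_map(parcellation)
    assignments: dict[tuple[int, int], list[int]] = {}
    n_unassigned = n_self = 0
    for idx, s in enumerate(t.streamlines):
        na = voxel_to_node.get(t.grid.voxel_of(s.points[0]))
        nb = voxel_to_node.get(t.grid.voxel_of(s.points[-1]))
        if na is None or nb is None:
            n_unassigned += 1
        elif na == nb:
            n_self += 1
        else:
            pair = (na, nb) if na < nb else (nb, na)
            assignments.setdefault(pair, []).append(idx)
    logger.info(
        "segmented %d streamlines: %d assigned to %d edges, %d unassigned, %d self-loops",
        len(t.streamlines),
        len(t.streamlines) - n_unassigned - n_self,
        len(assignments),
        n_unassigned,
        n_self,
    )
    return assignments


def _traversed_voxels(
    points: np.ndarray, grid, step: float | None = None
) -> set[tuple[int, int, int]]:
    """Voxels visited by a polyline, by point-in-voxel tests on a dense
    resampling (default step: one quarter of the smallest voxel edge)."""
    if step is None:
        step = min(grid.voxel_edges) / 4.0
    pts = np.asarray(points, dtype=float)
    dense = [pts[:1]]
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    for k in range(len(seg)):
        if seg_len[k] == 0:
            continue
        n = max(int(np.ceil(seg_len[k] / step)), 1)
        frac = (np.arange(1, n + 1) / n)[:, None]
        dense.append(pts[k] + frac * seg[k])
    dense_pts = np.vstack(dense)
    idx = np.floor(dense_pts / np.asarray(grid.voxel_edges)).astype(int)
    return {tuple(v) for v in idx}


def edge_occupancy(
    t: Tractogram,
    parcellation_by_id: Mapping[int, NodeRegion],
    pair: tuple[int, int],
    candidate_refs: Sequence[int],
) -> EdgeOccupancy:
    """Build R for an edge and retain the streamlines seeded inside it."""
    i, j = pair
    traversed: set[tuple[int, int, int]] = set()
    for ref in candidate_refs:
        traversed |= _traversed_voxels(t.streamlines[ref].points, t.grid)
    R = traversed - set(parcellation_by_id[i].voxel_members) - set(
        parcellation_by_id[j].voxel_members
    )
    retained = tuple(ref for ref in candidate_refs if t.streamlines[ref].seed_voxel in R)
    return EdgeOccupancy((i, j), frozenset(R), retained)


def characteristic_filter(s: Streamline, occ: EdgeOccupancy) -> int:
    """Indicator chi_R: 1 iff the streamline's seed voxel lies in the edge's
    white-matter voxel set R (which excludes both nodes' member voxels)."""
    return 1 if tuple(s.seed_voxel) in occ.voxels else 0


def edge_weight(
    t: Tractogram,
    occ: EdgeOccupancy,
    node_i: NodeRegion,
    node_j: NodeRegion,
) -> float:
    """The dimensionless edge weight over the retained streamlines."""
    area_sum = node_i.surface_area_mm2 + node_j.surface_area_mm2
    if area_sum <= 0:
        raise InvalidGeometryError("node surface areas sum to zero")
    if t.seeds_per_voxel <= 0:
        raise InvalidGeometryError("seeds per voxel must be positive")
    inv_lengths = sum(
        1.0 / streamline_arclength(t.streamlines[ref]) for ref in occ.streamline_refs
    )
    return (2.0 / area_sum) * (t.grid.voxel_volume / t.seeds_per_voxel) * inv_lengths


def build_connectome(t: Tractogram, parcellation: Sequence[NodeRegion]) -> Connectome:
    """Segment, filter and weight every node pair into a connectome.

    No threshold is applied; the matrix is symmetric with zero diagonal.
    An empty tractogram yields an all-zero matrix with a warning.
    """
    nodes = sorted(parcellation, key=lambda n: n.node_id)
    by_id = {n.node_id: n for n in nodes}
    order = {n.node_id: k for k, n in enumerate(nodes)}
    if len(t.streamlines) == 0:
        warnings.warn("empty tractogram: building an all-zero connectome", stacklevel=2)
    assignments = segment_tractogram(t, nodes)
    W = np.zeros((len(nodes), len(nodes)))
    for pair, refs in assignments.items():
        occ = edge_occupancy(t, by_id, pair, refs)
        w = edge_weight(t, occ, by_id[pair[0]], by_id[pair[1]])
        a, b = order[pair[0]], order[pair[1]]
        W[a, b] = W[b, a] = w
    return Connectome([n.name for n in nodes], W, nodes)


# ---------------------------------------------------------------------------
# alternative FA weighting
# ---------------------------------------------------------------------------

def fa_edge_weight(occ: EdgeOccupancy, fa: ScalarField) -> float:
    """Mean fractional anisotropy over the edge's M white-matter voxels."""
    if occ.n_voxels == 0:
        raise UndefinedEdgeError(f"edge {occ.node_pair} has no white-matter voxels")
    vals = [fa.values[v] for v in occ.voxels]
    return float(np.mean(vals))


def build_fa_connectome(
    t: Tractogram, parcellation: Sequence[NodeRegion], fa: ScalarField
) -> Connectome:
    """Connectome under the traditional mean-FA edge weighting, on the same
    edge supports (R sets) as the dimensionless weighting."""
    if fa.grid.shape != t.grid.shape:
        raise ValueError("FA field grid does not match tractogram grid")
    nodes = sorted(parcellation, key=lambda n: n.node_id)
    by_id = {n.node_id: n for n in nodes}
    order = {n.node_id: k for k, n in enumerate(nodes)}
    assignments = segment_tractogram(t, nodes)
    W = np.zeros((len(nodes), len(nodes)))
    for pair, refs in assignments.items():
        occ = edge_occupancy(t, by_id, pair, refs)
        if occ.n_voxels == 0:
            continue  # edge absent under FA weighting
        w = fa_edge_weight(occ, fa)
        a, b = order[pair[0]], order[pair[1]]
        W[a, b] = W[b, a] = w
    return Connectome([n.name for n in nodes], W, nodes)
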