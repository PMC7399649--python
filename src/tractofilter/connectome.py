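"""Endpoint-to-ROI assignment, bundle grouping and connectome construction.

A streamline connects two gray-matter ROIs when *both* of its endpoints can
be assigned: an endpoint is assigned to the ROI of the voxel it falls in,
or else to the nearest labeled voxel centre within the assignment radius
(default 2 mm, Euclidean distance in world mm). Streamlines with an
unassignable endpoint, or with both endpoints in the same ROI, are excluded
from bundles and connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import Parcellation
from .solvers import GroupStructure
from .tractogram import Tractogram

_EDGE_EPS = 1e-12  # edge weights at or below this are treated as absent


@dataclass
class EndpointAssignment:
    """Per-streamline ROI pair, ordered ``roi_a <= roi_b``; -1 = unassigned."""

    pairs: np.ndarray  # (n, 2) int
    roi_labels: list[int]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def assigned(self) -> np.ndarray:
        return np.all(self.pairs > 0, axis=1)

    @property
    def n_assigned(self) -> int:
        return int(self.assigned.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"streamline": np.arange(len(self.pairs)),
                             "roi_a": self.pairs[:, 0], "roi_b": self.pairs[:, 1]})

    def subset(self, indices) -> "EndpointAssignment":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EndpointAssignment(self.pairs[idx], list(self.roi_labels))


def assign_endpoints(tractogram: Tractogram, parcellation: Parcellation,
                     radius: float = 2.0) -> EndpointAssignment:
    """Assign each streamline's endpoints to ROIs within ``radius`` mm.

    An endpoint inside a labeled voxel takes that label directly; otherwise
    it takes the label of the nearest labeled voxel centre within the
    radius, ties broken toward the lower label. Self-connections are
    recorded as unassigned.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = parcellation.labels
    roi_lin = np.flatnonzero(labels.ravel(order="F") > 0)
    if len(roi_lin) == 0:
        raise ValueError("parcellation has no labeled voxels")
    grid = parcellation.grid
    roi_idx = grid.unravel(roi_lin)
    centers = grid.voxel_centers(roi_idx)
    roi_of_center = labels.ravel(order="F")[roi_lin]
    tree = cKDTree(centers)

    def assign_point(p: np.ndarray) -> int:
        lab = parcellation.label_at(p)
        if lab > 0:
            return lab
        d, _ = tree.query(p)
        if d > radius:
            return -1
        cand = tree.query_ball_point(p, d + 1e-9)
        return int(np.min(roi_of_center[cand]))

    pairs = np.empty((len(tractogram), 2), np.int64)
    for i, sl in enumerate(tractogram):
        a, b = assign_point(sl[0]), assign_point(sl[-1])
        if a < 0 or b < 0 or a == b:
            pairs[i] = (-1, -1)
        else:
            pairs[i] = (min(a, b), max(a, b))
    return EndpointAssignment(pairs, parcellation.roi_labels)


@dataclass
class BundleGrouping:
    """Streamlines grouped by distinct unordered ROI pair."""

    pair_list: list[tuple[int, int]]
    members: list[np.ndarray]  # streamline indices per pair

    def to_group_structure(self, n_columns: int | None = None,
                           exempt=()) -> GroupStructure:
        """As a solver GroupStructure over matrix columns.

        Valid when matrix columns 0..n-1 are exactly the grouped
        streamlines in order (drop unassigned streamlines first), with any
        trailing isotropic columns listed in ``exempt``.
        """
        n_sl = int(max((m.max() for m in self.members if len(m)), default=-1)) + 1
        n_columns = n_columns if n_columns is not None else n_sl
        return GroupStructure([m.copy() for m in self.members], n_columns,
                              np.asarray(sorted(exempt), np.int64))


def group_by_pairs(assignment: EndpointAssignment) -> BundleGrouping:
    """One group per distinct ROI pair; unassigned streamlines excluded."""
    mask = assignment.assigned
    if not mask.any():
        raise ValueError("no assigned streamlines to group")
    pairs = assignment.pairs[mask]
    order = np.flatnonzero(mask)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    members = [order[inverse == k] for k in range(len(uniq))]
    return BundleGrouping([(int(a), int(b)) for a, b in uniq], members)


@dataclass
class Connectome:
    """Symmetric non-negative ROI x ROI edge-weight matrix, zero diagonal."""

    roi_labels: list[int]
    matrix: np.ndarray = field(repr=False)
    weight_definition: str = "streamline_count"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        r = len(self.roi_labels)
        if m.shape != (r, r):
            raise ValueError(f"matrix shape {m.shape} != ({r}, {r})")
        if not np.allclose(m, m.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("self-connections are excluded (diagonal must be zero)")
        if not np.all(np.isfinite(m)) or m.min() < 0:
            raise ValueError("edge weights must be finite and non-negative")
        self.matrix = m

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered ROI-label pairs with weight above the absence threshold."""
        r = self.n_rois
        out = set()
        for i in range(r):
            for j in range(i + 1, r):
                if self.matrix[i, j] > _EDGE_EPS:
                    out.add((self.roi_labels[i], self.roi_labels[j]))
        return out

    def edge_weight(self, a: int, b: int) -> float:
        i, j = self.roi_labels.index(a), self.roi_labels.index(b)
        return float(self.matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.roi_labels, columns=self.roi_labels)

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(a, b, self.edge_weight(a, b)) for a, b in sorted(self.edge_set())]
        return pd.DataFrame(rows, columns=["roi_a", "roi_b", "weight"])

    @classmethod
    def from_edges(cls, roi_labels, edges, weight_definition="fiber_count") -> "Connectome":
        """Build from (roi_a, roi_b, weight) triples."""
        roi_labels = sorted(int(v) for v in roi_labels)
        pos = {v: i for i, v in enumerate(roi_labels)}
        m = np.zeros((len(roi_labels), len(roi_labels)))
        for a, b, w in edges:
            if a == b:
                raise ValueError("self-connection in edge list")
            m[pos[int(a)], pos[int(b)]] += w
            m[pos[int(b)], pos[int(a)]] += w
        return cls(roi_labels, m, weight_definition)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, weight_definition="streamline_count") -> "Connectome":
        labels = [int(v) for v in df.columns]
        return cls(labels, df.to_numpy(float), weight_definition)


def build_connectome(assignment: EndpointAssignment,
                     weights: np.ndarray | None = None,
                     weight_definition: str = "streamline_count") -> Connectome:
    """Accumulate assigned streamlines into a weighted connectome.

    ``streamline_count`` counts assigned streamlines per edge;
    ``sum_of_weights`` sums the per-streamline solver weights (required
    argument then), so zero-weight streamlines contribute nothing and fully
    silenced bundles disappear from the connectome.
    """
    if weight_definition not in ("streamline_count", "sum_of_weights"):
        raise ValueError(f"unknown weight definition {weight_definition!r}")
    if weight_definition == "sum_of_weights":
        if weights is None:
            raise ValueError("sum_of_weights requires per-streamline weights")
        weights = np.asarray(weights, float)
        if weights.shape != (len(assignment),):
            raise ValueError("weights length must match number of streamlines")
        if np.any(weights < 0):
            raise ValueError("negative streamline weights")
    labels = assignment.roi_labels
    pos = {v: i for i, v in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for i, (a, b) in enumerate(assignment.pairs):
        if a <= 0:
            continue
        w = 1.0 if weight_definition == "streamline_count" else float(weights[i])
        m[pos[int(a)], pos[int(b)]] += w
        m[pos[int(b)], pos[int(a)]] += w
    m[m <= _EDGE_EPS] = 0.0
    return Connectome(list(labels), m, weight_definition)


def network_density(connectome: Connectome) -> float:
    """Fraction of possible distinct ROI pairs that carry an edge."""
    r = connectome.n_rois
    if r < 2:
        raise ValueError("network density needs at least 2 ROIs")
    return len(connectome.edge_set()) / (r * (r - 1) / 2)
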