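"""Sparse forward operator mapping streamline contributions to voxel data.

The linear model is ``y = A x`` with ``x >= 0``. Two row spaces are
supported:

* **length mode** — one row per voxel; a streamline column holds its exact
  geometric length inside each traversed voxel divided by the voxel volume,
  so that with ``x`` interpreted as cross-sectional area (mm^2) the product
  ``A x`` is a dimensionless intra-axonal volume fraction per voxel.
* **stickball mode** — one row per (voxel, gradient direction); a streamline
  column holds the signal of a "stick" (purely anisotropic tensor) oriented
  along the streamline's local direction in each traversed voxel, and each
  optional isotropic column holds a "ball" signal in the rows of one voxel.
  This is the forward model of the four-voxel teaching example.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grid import VoxelGrid
from .tractogram import Tractogram


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def segment_lengths(streamline: np.ndarray, grid: VoxelGrid) -> dict[int, float]:
    """Exact arc length of a polyline inside each voxel it traverses.

    Returns a map from linear voxel index (x-fastest raster order) to mm of
    polyline inside that voxel. Portions outside the grid box are clipped.
    Each linear segment is cut at every voxel-boundary plane it crosses and
    each sub-segment is attributed to the voxel containing its midpoint,
    which implements the half-open voxel convention.
    """
    pts = np.asarray(streamline, float)
    origin = np.asarray(grid.origin)
    vs = np.asarray(grid.voxel_size)
    dims = np.asarray(grid.dims)

    out: dict[int, float] = {}
    q = (pts - origin) / vs  # voxel-unit coordinates
    for a in range(len(pts) - 1):
        q0, q1 = q[a], q[a + 1]
        d = q1 - q0
        seg_mm = np.linalg.norm((pts[a + 1] - pts[a]))
        if seg_mm == 0.0:
            continue
        # parameter values where the segment crosses integer boundary planes
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            lo, hi = sorted((q0[ax], q1[ax]))
            for k in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
                t = (k - q0[ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts = np.unique(ts)
        mids = q0 + np.outer(0.5 * (ts[:-1] + ts[1:]), d)
        vox = np.floor(mids).astype(np.int64)
        inside = np.all((vox >= 0) & (vox < dims), axis=1)
        lengths = seg_mm * np.diff(ts)
        lin = vox[:, 0] + dims[0] * (vox[:, 1] + dims[1] * vox[:, 2])
        for ok, li, ln in zip(inside, lin, lengths):
            if ok and ln > 0.0:
                out[int(li)] = out.get(int(li), 0.0) + float(ln)
    return out


def fibonacci_directions(n: int, seed: int | None = None) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (golden-spiral),
    optionally given a small random rotation so direction sets differ by seed."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if seed is not None:
        rng = np.random.default_rng(seed)
        mat = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(mat) < 0:
            mat[:, 0] = -mat[:, 0]
        dirs = dirs @ mat.T
    return dirs


# ---------------------------------------------------------------------------
# operator
# ---------------------------------------------------------------------------

@dataclass
class StickBallParams:
    """Two-compartment signal constants for the teaching forward model.

    Diffusivities are in mm^2/s, b-value in s/mm^2. Defaults: parallel
    diffusivity 1.7e-3 (stick), free-water 3.0e-3 (ball), b = 3000, with 30
    near-uniform gradient directions.
    """

    b_value: float = 3000.0
    d_parallel: float = 1.7e-3
    d_iso: float = 3.0e-3
    directions: np.ndarray = field(default_factory=lambda: fibonacci_directions(30))

    def stick_signal(self, fiber_dir: np.ndarray) -> np.ndarray:
        u = np.asarray(fiber_dir, float)
        u = u / np.linalg.norm(u)
        dots = self.directions @ u
        return np.exp(-self.b_value * self.d_parallel * dots**2)

    def ball_signal(self) -> np.ndarray:
        n = len(self.directions)
        return np.full(n, np.exp(-self.b_value * self.d_iso))


@dataclass
class ContributionMatrix:
    """Sparse operator ``A`` with column bookkeeping.

    ``column_kinds[j]`` is ``"streamline"`` or ``"isotropic"``. In length
    mode rows are voxels; in stickball mode row ``v * n_dirs + m`` is
    (voxel v, measurement m).
    """

    matrix: sp.csc_matrix
    column_kinds: np.ndarray
    grid: VoxelGrid
    mode: str
    n_dirs: int = 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def streamline_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_kinds == "streamline")

    @property
    def isotropic_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_kinds == "isotropic")

    def subset_columns(self, cols) -> "ContributionMatrix":
        cols = np.asarray(cols)
        return ContributionMatrix(self.matrix[:, cols].tocsc(), self.column_kinds[cols],
                                  self.grid, self.mode, self.n_dirs)

    def to_coo_text(self, path) -> None:
        """Serialize as whitespace-separated (row, col, value) triplets."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write(f"% {self.shape[0]} {self.shape[1]} {coo.nnz} mode={self.mode}\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r} {c} {v:.17g}\n")


def build_matrix(tractogram: Tractogram, grid: VoxelGrid, mode: str = "length",
                 include_isotropic: bool = False,
                 model_params: StickBallParams | None = None) -> ContributionMatrix:
    """Assemble the forward operator from a tractogram.

    Column order is the input streamline order followed, when
    ``include_isotropic`` is set, by one isotropic column per voxel in
    raster order. A streamline that traverses no in-grid voxel would yield
    an all-zero column and is rejected with its index.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    if mode not in ("length", "stickball"):
        raise ValueError(f"unknown mode {mode!r}")

    n_v = grid.n_voxels
    if mode == "length":
        n_dirs = 1
        n_rows = n_v
    else:
        model_params = model_params or StickBallParams()
        n_dirs = len(model_params.directions)
        n_rows = n_v * n_dirs

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    vox_vol = grid.voxel_volume

    for j, sl in enumerate(tractogram):
        lengths = segment_lengths(sl, grid)
        if not lengths:
            raise ValueError(f"streamline {j} traverses no in-grid voxel (zero column)")
        vox_idx = np.fromiter(lengths.keys(), np.int64)
        vox_len = np.fromiter(lengths.values(), float)
        if mode == "length":
            rows.append(vox_idx)
            cols.append(np.full(len(vox_idx), j, np.int64))
            vals.append(vox_len / vox_vol)
        else:
            dirs = _local_directions(sl, grid, vox_idx)
            for vi, u in zip(vox_idx, dirs):
                sig = model_params.stick_signal(u)
                rows.append(vi * n_dirs + np.arange(n_dirs, dtype=np.int64))
                cols.append(np.full(n_dirs, j, np.int64))
                vals.append(sig)

    kinds = ["streamline"] * len(tractogram)
    if include_isotropic:
        base = len(tractogram)
        for v in range(n_v):
            if mode == "length":
                rows.append(np.array([v], np.int64))
                cols.append(np.array([base + v], np.int64))
                vals.append(np.array([1.0]))
            else:
                sig = model_params.ball_signal()
                rows.append(v * n_dirs + np.arange(n_dirs, dtype=np.int64))
                cols.append(np.full(n_dirs, base + v, np.int64))
                vals.append(sig)
        kinds += ["isotropic"] * n_v

    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, len(kinds)),
    ).tocsc()
    return ContributionMatrix(mat, np.asarray(kinds, object), grid, mode, n_dirs)


def _local_directions(streamline: np.ndarray, grid: VoxelGrid,
                      vox_linear: np.ndarray) -> list[np.ndarray]:
    """Length-weighted mean direction of a streamline within each listed voxel."""
    pts = np.asarray(streamline, float)
    origin = np.asarray(grid.origin)
    vs = np.asarray(grid.voxel_size)
    dims = np.asarray(grid.dims)
    accum = {int(v): np.zeros(3) for v in vox_linear}
    q = (pts - origin) / vs
    for a in range(len(pts) - 1):
        d = q[a + 1] - q[a]
        seg = pts[a + 1] - pts[a]
        seg_mm = np.linalg.norm(seg)
        if seg_mm == 0.0:
            continue
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            lo, hi = sorted((q[a][ax], q[a + 1][ax]))
            for k in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
                t = (k - q[a][ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts = np.unique(ts)
        mids = q[a] + np.outer(0.5 * (ts[:-1] + ts[1:]), d)
        vox = np.floor(mids).astype(np.int64)
        lin = vox[:, 0] + dims[0] * (vox[:, 1] + dims[1] * vox[:, 2])
        u = seg / seg_mm
        for li, dt in zip(lin, np.diff(ts)):
            if int(li) in accum:
                accum[int(li)] += u * (dt * seg_mm)
    dirs = []
    for v in vox_linear:
        vec = accum[int(v)]
        n = np.linalg.norm(vec)
        dirs.append(vec / n if n > 0 else np.array([1.0, 0.0, 0.0]))
    return dirs


def predict(A: ContributionMatrix, x: np.ndarray) -> np.ndarray:
    """Forward prediction ``A x`` for non-negative contributions ``x``."""
    x = np.asarray(x, float)
    if x.shape != (A.n_columns,):
        raise ValueError(f"x has shape {x.shape}, expected ({A.n_columns},)")
    if np.any(x < 0):
        raise ValueError("contributions must be non-negative")
    return A.matrix @ x
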