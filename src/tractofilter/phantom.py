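"""Self-contained digital connectivity phantoms with known ground truth.

A phantom is a voxel grid carrying (i) a gray-matter parcellation whose
ROIs sit as spherical caps on the grid boundary, (ii) a set of ground-truth
fiber bundles — smooth cubic-spline centerlines between ROI pairs, each
populated by a configurable number of fibers spread over the bundle radius
— and (iii) an intra-axonal signal-fraction map accumulated from the exact
geometry of the ground-truth fibers (segment length x fiber cross-section
per voxel).

Candidate tractograms mix faithful copies of the true fibers with
controlled false positives built by *splicing* two true bundles where they
cross, which mimics the dominant mechanism by which tractography produces
anatomically implausible connections at fiber crossings.

A separate four-voxel stick-and-ball instance with three fibers and known
coefficients serves as a fully worked teaching example of the linear
forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .connectome import Connectome
from .forward import (ContributionMatrix, StickBallParams, build_matrix,
                      fibonacci_directions, segment_lengths)
from .grid import Parcellation, VoxelGrid
from .tractogram import Tractogram


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """One ground-truth bundle: centerline between two ROIs plus geometry."""

    roi_a: int
    roi_b: int
    centerline: np.ndarray  # (m, 3) world mm
    radius: float           # mm, maximum perpendicular spread of its fibers
    fiber_count: int


@dataclass
class Phantom:
    """Ground-truth scene: parcellation, bundles, fibers and fraction map."""

    grid: VoxelGrid
    parcellation: Parcellation
    true_bundles: list[Bundle]
    true_streamlines: Tractogram   # labels carry {"bundle": k, "pair": (a, b)}
    fraction_map: np.ndarray       # 3D, values in [0, 1]
    true_connectome: Connectome    # fiber counts per true edge
    fiber_area: float              # mm^2 cross-section of one ground-truth fiber

    @property
    def y_vector(self) -> np.ndarray:
        """Fraction map flattened in the forward operator's row order."""
        return self.fraction_map.ravel(order="F")

    @property
    def true_pairs(self) -> set[tuple[int, int]]:
        return {(min(b.roi_a, b.roi_b), max(b.roi_a, b.roi_b)) for b in self.true_bundles}


@dataclass
class ToyInstance:
    """The four-voxel / three-fiber stick-and-ball teaching instance.

    Columns of ``matrix``: fibers 1-3, then one ball (isotropic) column per
    voxel 1-4. ``incidence`` maps 1-based fiber number to the 1-based
    voxels it traverses: fiber 1 -> {1, 2}, fiber 2 -> {1, 3},
    fiber 3 -> {2, 3, 4}. The noiseless signal is generated from
    ``x_true = (1, 1, 0, 0, 0, 0, 1)``: fibers 1 and 2 are real, fiber 3 is
    a false positive, and only voxel 4 contains free water.
    """

    matrix: ContributionMatrix
    signal: np.ndarray
    x_true: np.ndarray
    incidence: dict[int, tuple[int, ...]]
    tractogram: Tractogram
    grid: VoxelGrid


# ---------------------------------------------------------------------------
# fraction map
# ---------------------------------------------------------------------------

def compute_fraction_map(grid_or_phantom, streamlines: Tractogram,
                         area_per_fiber, cap: float = 1.0) -> np.ndarray:
    """Accumulate per-voxel fiber volume fraction from streamline geometry.

    Each streamline deposits (length inside voxel) x (its cross-sectional
    area, mm^2) / (voxel volume) into every voxel it traverses. Values
    above ``cap`` are clipped with a warning. ``area_per_fiber`` may be a
    scalar or a per-streamline array.
    """
    grid = grid_or_phantom.grid if isinstance(grid_or_phantom, Phantom) else grid_or_phantom
    areas = np.broadcast_to(np.asarray(area_per_fiber, float), (len(streamlines),))
    flat = np.zeros(grid.n_voxels)
    vol = grid.voxel_volume
    for sl, area in zip(streamlines, areas):
        for lin, length in segment_lengths(sl, grid).items():
            flat[lin] += length * area / vol
    if flat.max() > cap:
        warnings.warn(f"fraction map peak {flat.max():.3g} exceeds cap {cap}; clipping")
        flat = np.minimum(flat, cap)
    return flat.reshape(grid.dims, order="F")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _place_roi_centers(rng, grid: VoxelGrid, n_rois: int, roi_radius: float,
                       max_attempts: int) -> np.ndarray:
    """ROI centres on the grid boundary faces, pulled 1 mm inward, with a
    minimum pairwise separation so caps never overlap."""
    lo = np.asarray(grid.origin)
    hi = lo + grid.extent
    min_sep = 2.0 * roi_radius + 1.0
    centers: list[np.ndarray] = []
    for _ in range(max_attempts):
        if len(centers) == n_rois:
            break
        face = rng.integers(6)
        ax, side = face % 3, face // 3
        p = np.array([rng.uniform(lo[a] + roi_radius, hi[a] - roi_radius)
                      for a in range(3)])
        p[ax] = (lo[ax] + 1.0) if side == 0 else (hi[ax] - 1.0)
        if all(np.linalg.norm(p - c) >= min_sep for c in centers):
            centers.append(p)
    if len(centers) < n_rois:
        raise RuntimeError(
            f"could not place {n_rois} ROI centres with separation {min_sep:.1f} mm "
            f"on a grid of extent {grid.extent} after {max_attempts} attempts")
    return np.asarray(centers)


def _label_caps(grid: VoxelGrid, centers: np.ndarray, roi_radius: float) -> np.ndarray:
    flat = np.zeros(grid.n_voxels, np.int64)
    all_idx = grid.unravel(np.arange(grid.n_voxels))
    vox_centers = grid.voxel_centers(all_idx)
    for r, c in enumerate(centers, start=1):
        within = np.linalg.norm(vox_centers - c, axis=1) <= roi_radius
        flat[within] = r
    return flat.reshape(grid.dims, order="F")


def _bundle_centerline(rng, grid: VoxelGrid, a: np.ndarray, b: np.ndarray,
                       n_samples: int) -> np.ndarray:
    """Cubic spline from ROI centre a to b through two interior control
    points near the grid centre, so bundles cross each other there."""
    mid = np.asarray(grid.origin) + 0.5 * grid.extent
    sigma = float(np.min(grid.extent)) / 10.0
    c1 = mid + rng.normal(0.0, sigma, 3)
    c2 = mid + rng.normal(0.0, sigma, 3)
    ctrl = np.asarray([a, c1, c2, b])
    # chord-length parameterization keeps the curve well behaved
    d = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(d)])
    t /= t[-1]
    spline = CubicSpline(t, ctrl, axis=0)
    return spline(np.linspace(0.0, 1.0, n_samples))


def _perp_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(v, u)


def _bundle_fibers(rng, bundle_centerline: np.ndarray, radius: float,
                   n_fibers: int, jitter_mm: float = 0.0) -> list[np.ndarray]:
    """Fibers = centerline + constant perpendicular offset within the bundle
    radius, tapered to zero at the endpoints so every fiber terminates at
    the ROI; optional smooth low-frequency jitter emulates tracking wobble."""
    m = len(bundle_centerline)
    t = np.linspace(0.0, 1.0, m)
    envelope = np.sqrt(np.clip(np.sin(np.pi * t), 0.0, 1.0))
    u, w = _perp_basis(bundle_centerline[-1] - bundle_centerline[0])
    fibers = []
    for _ in range(n_fibers):
        rho = radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        offset = rho * (np.cos(theta) * u + np.sin(theta) * w)
        pts = bundle_centerline + envelope[:, None] * offset
        if jitter_mm > 0.0:
            knots = rng.normal(0.0, jitter_mm, (4, 3))
            tk = np.linspace(0.0, 1.0, 4)
            jit = CubicSpline(tk, knots, axis=0)(t)
            pts = pts + envelope[:, None] * jit
        fibers.append(pts)
    return fibers


def make_phantom(n_rois: int = 10, n_bundles: int | None = None,
                 density: float | None = None,
                 grid_dims: tuple[int, int, int] = (20, 20, 20),
                 voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 seed: int = 0, radius_range: tuple[float, float] = (1.5, 4.0),
                 fibers_per_bundle: int = 12, roi_radius: float = 2.0,
                 peak_fraction: float = 0.8, centerline_samples: int = 64,
                 noise_sigma: float = 0.0, max_attempts: int = 20000) -> Phantom:
    """Generate a random phantom with ``n_bundles`` ground-truth bundles.

    Either ``n_bundles`` or ``density`` (fraction of the R(R-1)/2 possible
    edges, rounded up) selects the number of bundles. Bundle radii are
    drawn uniformly from ``radius_range`` (mm). The fraction map is scaled
    so its peak equals ``peak_fraction``; optional additive Gaussian noise
    of ``noise_sigma`` is applied afterwards (clipped to [0, 1]).
    Deterministic given the seed.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    n_possible = n_rois * (n_rois - 1) // 2
    if density is not None:
        if not (0.0 < density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        n_bundles = int(np.ceil(density * n_possible))
    if n_bundles is None:
        raise ValueError("give either n_bundles or density")
    if not (0 <= n_bundles <= n_possible):
        raise ValueError(f"n_bundles = {n_bundles} exceeds possible pairs {n_possible}")

    rng = np.random.default_rng(seed)
    grid = VoxelGrid(grid_dims, voxel_size)
    centers = _place_roi_centers(rng, grid, n_rois, roi_radius, max_attempts)
    parcellation = Parcellation(grid, _label_caps(grid, centers, roi_radius))

    all_pairs = [(a, b) for a in range(1, n_rois + 1) for b in range(a + 1, n_rois + 1)]
    chosen = [all_pairs[i] for i in rng.choice(n_possible, n_bundles, replace=False)] \
        if n_bundles else []

    bundles: list[Bundle] = []
    fibers: list[np.ndarray] = []
    labels: list[dict] = []
    for k, (a, b) in enumerate(chosen):
        radius = float(rng.uniform(*radius_range))
        cl = _bundle_centerline(rng, grid, centers[a - 1], centers[b - 1],
                                centerline_samples)
        bundles.append(Bundle(a, b, cl, radius, fibers_per_bundle))
        for f in _bundle_fibers(rng, cl, radius, fibers_per_bundle):
            fibers.append(f)
            labels.append({"bundle": k, "pair": (a, b), "is_true": True})

    if fibers:
        tract = Tractogram(fibers, labels)
        raw = compute_fraction_map(grid, tract, 1.0, cap=np.inf)
        fiber_area = float(peak_fraction / raw.max())
        fraction_map = raw * fiber_area
    else:
        tract = Tractogram([], [])
        fiber_area = 1.0
        fraction_map = np.zeros(grid.dims)
    if noise_sigma > 0.0:
        fraction_map = np.clip(
            fraction_map + rng.normal(0.0, noise_sigma, fraction_map.shape), 0.0, 1.0)

    truth = Connectome.from_edges(range(1, n_rois + 1),
                                  [(a, b, fibers_per_bundle) for a, b in chosen],
                                  "fiber_count")
    return Phantom(grid, parcellation, bundles, tract, fraction_map, truth, fiber_area)


# ---------------------------------------------------------------------------
# candidate tractogram with spliced false positives
# ---------------------------------------------------------------------------

def _closest_approach(p: np.ndarray, q: np.ndarray) -> tuple[int, int, float]:
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return int(i), int(j), float(d[i, j])


def enumerate_false_pairs(phantom: Phantom) -> list[dict]:
    """All ROI pairs reachable by splicing two crossing true bundles.

    Two bundles "cross" when their centerlines approach within the sum of
    their radii. Each crossing yields up to four endpoint combinations;
    combinations reproducing a true edge or a self-connection are dropped,
    and each reachable pair is listed once (first constructible splice).
    """
    true_pairs = phantom.true_pairs
    found: dict[tuple[int, int], dict] = {}
    nb = len(phantom.true_bundles)
    for i in range(nb):
        for j in range(i + 1, nb):
            bi, bj = phantom.true_bundles[i], phantom.true_bundles[j]
            pi, pj, dist = _closest_approach(bi.centerline, bj.centerline)
            if dist > bi.radius + bj.radius:
                continue
            ends_i = {True: bi.roi_a, False: bi.roi_b}   # front kept -> starts at roi_a
            ends_j = {True: bj.roi_b, False: bj.roi_a}   # back kept -> ends at roi_b
            for keep_front_i in (True, False):
                for keep_back_j in (True, False):
                    a, b = ends_i[keep_front_i], ends_j[keep_back_j]
                    pair = (min(a, b), max(a, b))
                    if a == b or pair in true_pairs or pair in found:
                        continue
                    found[pair] = {"pair": pair, "bundle_i": i, "bundle_j": j,
                                   "idx_i": pi, "idx_j": pj,
                                   "keep_front_i": keep_front_i,
                                   "keep_back_j": keep_back_j}
    return [found[k] for k in sorted(found)]


def _splice(fiber_i: np.ndarray, fiber_j: np.ndarray, idx_i: int, idx_j: int,
            keep_front_i: bool, keep_back_j: bool) -> np.ndarray:
    part1 = fiber_i[: idx_i + 1] if keep_front_i else fiber_i[idx_i:][::-1]
    part2 = fiber_j[idx_j:] if keep_back_j else fiber_j[: idx_j + 1][::-1]
    return np.vstack([part1, part2])


def generate_candidate_tractogram(phantom: Phantom,
                                  streamlines_per_true_bundle: int | None = None,
                                  n_false_bundles: int = 0,
                                  streamlines_per_false_bundle: int = 8,
                                  jitter_mm: float = 0.2,
                                  seed: int = 0) -> Tractogram:
    """Candidate tractogram mixing true and spliced false-positive bundles.

    True streamlines re-trace each ground-truth bundle (fresh perpendicular
    offsets plus smooth jitter of amplitude ``jitter_mm``), so they follow
    the correct anatomy without duplicating the ground-truth fibers
    exactly. False streamlines splice the front of one such fiber onto the
    back of a fiber from a crossing bundle, producing streamlines that are
    locally plausible everywhere yet connect an ROI pair absent from the
    ground truth. Per-streamline labels record truth status and ROI pair;
    ``meta["n_reachable_negatives"]`` counts all constructible false pairs
    (the specificity denominator N).
    """
    rng = np.random.default_rng(seed)
    n_true = streamlines_per_true_bundle or (
        phantom.true_bundles[0].fiber_count if phantom.true_bundles else 0)

    per_bundle_fibers: list[list[np.ndarray]] = []
    streamlines: list[np.ndarray] = []
    labels: list[dict] = []
    for k, b in enumerate(phantom.true_bundles):
        fibers = _bundle_fibers(rng, b.centerline, b.radius, n_true, jitter_mm)
        per_bundle_fibers.append(fibers)
        pair = (min(b.roi_a, b.roi_b), max(b.roi_a, b.roi_b))
        for f in fibers:
            streamlines.append(f)
            labels.append({"is_true": True, "pair": pair, "bundle": k})

    candidates = enumerate_false_pairs(phantom)
    if n_false_bundles > len(candidates):
        raise ValueError(
            f"requested {n_false_bundles} false bundles but only "
            f"{len(candidates)} ROI pairs are reachable by splicing crossings")
    picked = [candidates[i] for i in
              rng.permutation(len(candidates))[:n_false_bundles]]
    for c in picked:
        for _ in range(streamlines_per_false_bundle):
            fi = per_bundle_fibers[c["bundle_i"]][rng.integers(n_true)]
            fj = per_bundle_fibers[c["bundle_j"]][rng.integers(n_true)]
            sl = _splice(fi, fj, c["idx_i"], c["idx_j"],
                         c["keep_front_i"], c["keep_back_j"])
            streamlines.append(sl)
            labels.append({"is_true": False, "pair": c["pair"], "bundle": None})

    return Tractogram(streamlines, labels, meta={
        "n_reachable_negatives": len(candidates),
        "true_pairs": sorted(phantom.true_pairs),
        "false_pairs": sorted(c["pair"] for c in picked),
        "jitter_mm": jitter_mm, "seed": seed,
    })


# ---------------------------------------------------------------------------
# four-voxel teaching instance
# ---------------------------------------------------------------------------

def make_toy_example(n_dirs: int = 30, b_value: float = 3000.0,
                     seed: int = 0) -> ToyInstance:
    """Build the four-voxel, three-fiber stick-and-ball instance.

    On a 2x2x1 grid of 1 mm voxels (voxel numbering: 1=(0,0), 2=(1,0),
    3=(0,1), 4=(1,1)), fiber 1 crosses voxels 1-2, fiber 2 crosses 1-3 and
    fiber 3 crosses 2, 4, 3. The forward matrix holds one stick column per
    fiber and one ball column per voxel; the signal is the noiseless
    forward prediction of ``x_true = (1, 1, 0, 0, 0, 0, 1)``.
    """
    if n_dirs < 7:
        raise ValueError("need at least 7 directions to identify 7 coefficients")
    grid = VoxelGrid((2, 2, 1))
    f1 = np.array([[0.1, 0.5, 0.5], [1.9, 0.5, 0.5]])
    f2 = np.array([[0.5, 0.1, 0.5], [0.5, 1.9, 0.5]])
    f3 = np.array([[1.5, 0.1, 0.5], [1.5, 1.1, 0.5], [0.5, 1.5, 0.5]])
    tract = Tractogram([f1, f2, f3],
                       [{"fiber": 1}, {"fiber": 2}, {"fiber": 3}])
    params = StickBallParams(b_value=b_value,
                             directions=fibonacci_directions(n_dirs, seed=seed))
    A = build_matrix(tract, grid, mode="stickball", include_isotropic=True,
                     model_params=params)
    x_true = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0])
    y = A.matrix @ x_true
    incidence = {1: (1, 2), 2: (1, 3), 3: (2, 3, 4)}
    return ToyInstance(A, y, x_true, incidence, tract, grid)
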