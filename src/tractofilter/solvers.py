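"""Non-negative least squares and (adaptive) group-lasso solvers.

All problems share the smooth data term ``||A x - y||_2^2`` over ``x >= 0``
and differ only in the penalty:

* NNLS — no penalty;
* group lasso — ``sum_g lambda_g ||x_g||_2`` over a partition of the
  columns into bundles, which drives whole groups to zero;
* lasso — the singleton-group special case.

The adaptive weights are ``lambda_g = lambda * |g| / ||x_g^NNLS||_2``, so a
large bundle that the unregularized fit already deems weak is penalized
hardest. Groups whose NNLS norm is exactly zero get an infinite weight and
are eliminated before the regularized solve.

The optimizer is a monotone FISTA (accelerated proximal gradient with the
exact non-negative block-shrinkage prox), with backtracking on the Lipschitz
estimate, so the objective trace is non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forward import ContributionMatrix


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class GroupStructure:
    """Partition of penalized matrix columns into bundles.

    ``groups`` is a list of integer index arrays (disjoint); ``exempt``
    columns (e.g. isotropic compartments) are never penalized, only kept
    non-negative. ``weights`` holds the per-group penalty scale
    ``lambda_g`` once computed (``np.inf`` marks a group forced inactive).
    """

    groups: list[np.ndarray]
    n_columns: int
    exempt: np.ndarray = field(default_factory=lambda: np.array([], np.int64))
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, np.int64) for g in self.groups]
        self.exempt = np.asarray(self.exempt, np.int64)
        seen = np.concatenate([*self.groups, self.exempt]) if (self.groups or len(self.exempt)) \
            else np.array([], np.int64)
        if len(seen) != len(np.unique(seen)):
            raise ValueError("groups and exempt columns must be disjoint")
        if len(seen) != self.n_columns or (len(seen) and (seen.min() < 0 or seen.max() >= self.n_columns)):
            raise ValueError("groups plus exempt columns must cover all columns exactly once")
        for g in self.groups:
            if len(g) < 1:
                raise ValueError("empty group")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != (len(self.groups),) or np.any(self.weights < 0):
                raise ValueError("weights must be one non-negative scalar per group")

    @property
    def cardinalities(self) -> np.ndarray:
        return np.asarray([len(g) for g in self.groups])

    @classmethod
    def singletons(cls, n_columns: int, exempt=()) -> "GroupStructure":
        ex = np.asarray(sorted(exempt), np.int64)
        groups = [np.array([j]) for j in range(n_columns) if j not in set(ex.tolist())]
        return cls(groups, n_columns, ex)

    def with_weights(self, weights: np.ndarray) -> "GroupStructure":
        return GroupStructure([g.copy() for g in self.groups], self.n_columns,
                              self.exempt.copy(), np.asarray(weights, float))


@dataclass
class SolverConfig:
    """Optimizer settings.

    ``lam`` is the global regularization strength (dimensionless trade-off);
    ``tol`` is the relative objective-change stopping tolerance.
    """

    lam: float = 0.0
    max_iter: int = 2000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class Solution:
    """Result of one solve: weights, objective trace and active bundles."""

    x: np.ndarray
    objective_trace: np.ndarray
    residual_norm: float
    active_groups: list[int]
    group_norms: np.ndarray
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "residual_norm": float(self.residual_norm),
            "objective_trace": [float(v) for v in self.objective_trace],
            "active_groups": [int(g) for g in self.active_groups],
            "group_norms": [float(v) for v in self.group_norms],
        }


_ACTIVE_EPS = 1e-12  # group norms below this count as inactive


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _as_sparse(A) -> sp.csr_matrix:
    if isinstance(A, ContributionMatrix):
        return A.matrix.tocsr()
    if sp.issparse(A):
        return A.tocsr()
    return sp.csr_matrix(np.asarray(A, float))


def spectral_norm_sq(A: sp.spmatrix, n_iter: int = 200, tol: float = 1e-10,
                     seed: int = 0) -> float:
    """Largest squared singular value of A by power iteration on A^T A."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    prev = 0.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return 0.0
        v = w / lam
        if abs(lam - prev) <= tol * max(lam, 1.0):
            break
        prev = lam
    return lam


def group_prox(v: np.ndarray, groups: GroupStructure,
               thresholds: np.ndarray) -> np.ndarray:
    """Exact prox of (non-negativity + per-group L2 penalty).

    For each group: project onto the non-negative orthant, then shrink the
    block norm by its threshold, zeroing the block when the projected norm
    does not exceed the threshold. Exempt columns are only projected.
    """
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds < 0):
        raise ValueError("thresholds must be >= 0")
    out = np.zeros_like(np.asarray(v, float))
    if len(groups.exempt):
        out[groups.exempt] = np.maximum(v[groups.exempt], 0.0)
    for g, t in zip(groups.groups, thresholds):
        p = np.maximum(v[g], 0.0)
        if t == 0.0:
            out[g] = p
            continue
        if not np.isfinite(t):
            continue  # forced inactive
        nrm = float(np.linalg.norm(p))
        out[g] = p * max(0.0, 1.0 - t / nrm) if nrm > t else 0.0
    return out


def compute_adaptive_weights(x_nnls: np.ndarray, groups: GroupStructure,
                             lam: float, sqrt_cardinality: bool = False) -> GroupStructure:
    """Per-group penalty ``lambda_g = lambda * |g| / ||x_g^NNLS||_2``.

    A group with zero NNLS norm receives ``np.inf``: the unregularized fit
    already found it unnecessary and it is fixed to zero in later solves.
    ``sqrt_cardinality`` swaps |g| for sqrt(|g|) (non-default variant).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x_nnls = np.asarray(x_nnls, float)
    if np.any(x_nnls < 0):
        raise ValueError("x_nnls must be non-negative")
    weights = np.empty(len(groups.groups))
    for i, g in enumerate(groups.groups):
        nrm = float(np.linalg.norm(x_nnls[g]))
        card = np.sqrt(len(g)) if sqrt_cardinality else float(len(g))
        if lam == 0.0:
            weights[i] = 0.0
        elif nrm == 0.0:
            weights[i] = np.inf
        else:
            weights[i] = lam * card / nrm
    return groups.with_weights(weights)


# ---------------------------------------------------------------------------
# monotone FISTA core
# ---------------------------------------------------------------------------

def _penalty(x: np.ndarray, groups: GroupStructure | None,
             weights: np.ndarray | None) -> float:
    if groups is None or weights is None:
        return 0.0
    tot = 0.0
    for g, w in zip(groups.groups, weights):
        if w > 0 and np.isfinite(w):
            tot += w * float(np.linalg.norm(x[g]))
    return tot


def _fista(A: sp.spmatrix, y: np.ndarray, groups: GroupStructure | None,
           weights: np.ndarray | None, config: SolverConfig,
           x0: np.ndarray | None = None) -> Solution:
    """Monotone FISTA on ``||Ax-y||^2 + penalty`` over ``x >= 0``.

    ``groups=None`` means pure non-negative projection (NNLS). The accepted
    iterate never increases the objective; the momentum point may. The step
    comes from a power-method estimate of ``2 ||A||_2^2`` and is halved
    (L doubled) whenever the smooth part exceeds its quadratic majorization.
    """
    n = A.shape[1]
    scale = None
    if groups is None:
        # pure NNLS: equilibrate column norms (exact reparameterization);
        # with a group penalty the block norms would no longer be plain L2
        col_norms = np.sqrt(np.asarray(A.multiply(A).sum(axis=0)).ravel())
        scale = 1.0 / np.where(col_norms > 0, col_norms, 1.0)
        A = (A @ sp.diags(scale)).tocsr()
    x = np.zeros(n) if x0 is None else np.maximum(np.asarray(x0, float).copy(), 0.0)
    if scale is not None:
        x /= scale
    L = 2.0 * spectral_norm_sq(A, seed=config.seed)
    if L == 0.0:
        warnings.warn("zero operator: returning x = 0")
        return _make_solution(np.zeros(n), [0.0], A, y, groups, weights, 0, True)
    L *= 1.01  # safety margin on the power-method estimate

    def smooth(v: np.ndarray) -> tuple[float, np.ndarray]:
        r = A @ v - y
        return float(r @ r), r

    def prox(v: np.ndarray, step: float) -> np.ndarray:
        if groups is None:
            return np.maximum(v, 0.0)
        return group_prox(v, groups, np.asarray(weights) * step)

    def descent_step(point: np.ndarray):
        """One backtracked proximal-gradient step from ``point``."""
        nonlocal L
        f_p, r_p = smooth(point)
        grad = 2.0 * (A.T @ r_p)
        for _ in range(60):
            z = prox(point - grad / L, 1.0 / L)
            f_z, _ = smooth(z)
            dz = z - point
            # quadratic majorization check (backtracking on L)
            if f_z <= f_p + grad @ dz + 0.5 * L * (dz @ dz) + 1e-12 * max(1.0, abs(f_p)):
                return z, f_z + _penalty(z, groups, weights)
            L *= 2.0
        raise RuntimeError("step backtracking exhausted; objective diverging")

    f_x, _ = smooth(x)
    F_x = f_x + _penalty(x, groups, weights)
    trace = [F_x]
    z_mom = x.copy()
    t_k = 1.0
    converged = False
    stall = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        z, F_z = descent_step(z_mom)
        if F_z > F_x:
            # adaptive restart: drop momentum and take a guaranteed-descent
            # step from the best iterate, keeping the trace monotone
            t_k = 1.0
            z, F_z = descent_step(x)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z_mom = z + ((t_k - 1.0) / t_next) * (z - x)
        rel_drop = (F_x - F_z) / max(F_x, 1e-300)
        x, F_x = z, F_z
        t_k = t_next
        trace.append(F_x)
        stall = stall + 1 if rel_drop < config.tol else 0
        if it > 1 and (stall >= 5 or F_x <= 1e-28 * max(1.0, trace[0])):
            converged = True
            break
    if scale is not None:
        x = x * scale
        A = A @ sp.diags(1.0 / scale)
    return _make_solution(x, trace, A, y, groups, weights, it, converged)


def _make_solution(x, trace, A, y, groups, weights, n_iter, converged) -> Solution:
    r = A @ x - y
    if groups is None:
        norms = np.array([])
        active: list[int] = []
    else:
        norms = np.array([float(np.linalg.norm(x[g])) for g in groups.groups])
        active = [i for i, v in enumerate(norms) if v > _ACTIVE_EPS]
    return Solution(x=x, objective_trace=np.asarray(trace),
                    residual_norm=float(np.linalg.norm(r)),
                    active_groups=active, group_norms=norms,
                    n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# public solves
# ---------------------------------------------------------------------------

def solve_nnls(A, y: np.ndarray, config: SolverConfig | None = None) -> Solution:
    """Minimize ``||Ax - y||_2^2`` over ``x >= 0`` (projected accelerated
    gradient)."""
    config = config or SolverConfig()
    Am = _as_sparse(A)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if y.shape != (Am.shape[0],):
        raise ValueError(f"y has shape {y.shape}, expected ({Am.shape[0]},)")
    return _fista(Am, y, None, None, config)


def solve_group_lasso(A, y: np.ndarray, groups: GroupStructure,
                      config: SolverConfig | None = None,
                      x0: np.ndarray | None = None) -> Solution:
    """Adaptive group-lasso solve.

    If ``groups.weights`` is unset, an internal NNLS solve supplies the
    adaptive weights at strength ``config.lam``. Groups with infinite
    weight are eliminated (their coefficients stay exactly zero) before the
    proximal-gradient solve on the remaining columns.
    """
    config = config or SolverConfig()
    Am = _as_sparse(A)
    y = np.asarray(y, float)
    if groups.n_columns != Am.shape[1]:
        raise ValueError("group structure does not match matrix columns")
    if groups.weights is None:
        base = solve_nnls(Am, y, SolverConfig(max_iter=config.max_iter,
                                              tol=config.tol, seed=config.seed))
        groups = compute_adaptive_weights(base.x, groups, config.lam)

    finite = [i for i, w in enumerate(groups.weights) if np.isfinite(w)]
    killed = [i for i, w in enumerate(groups.weights) if not np.isfinite(w)]
    if killed:
        keep_cols = np.sort(np.concatenate(
            [groups.exempt, *[groups.groups[i] for i in finite]]
            if (finite or len(groups.exempt)) else [np.array([], np.int64)]))
        remap = {int(c): k for k, c in enumerate(keep_cols)}
        sub = GroupStructure(
            [np.asarray([remap[int(c)] for c in groups.groups[i]]) for i in finite],
            len(keep_cols),
            np.asarray([remap[int(c)] for c in groups.exempt], np.int64),
            np.asarray([groups.weights[i] for i in finite]),
        )
        sol = _fista(Am[:, keep_cols].tocsr(), y, sub, sub.weights, config,
                     x0=None if x0 is None else np.asarray(x0)[keep_cols])
        x_full = np.zeros(Am.shape[1])
        x_full[keep_cols] = sol.x
        norms = np.array([float(np.linalg.norm(x_full[g])) for g in groups.groups])
        return Solution(x=x_full, objective_trace=sol.objective_trace,
                        residual_norm=sol.residual_norm,
                        active_groups=[i for i, v in enumerate(norms) if v > _ACTIVE_EPS],
                        group_norms=norms, n_iter=sol.n_iter, converged=sol.converged)
    return _fista(Am, y, groups, groups.weights, config, x0=x0)


def solve_lasso(A, y: np.ndarray, config: SolverConfig | None = None,
                exempt=()) -> Solution:
    """Adaptive lasso: singleton groups, per-column weights
    ``lambda / |x_i^NNLS|``."""
    Am = _as_sparse(A)
    if isinstance(A, ContributionMatrix) and not len(np.asarray(exempt)):
        exempt = A.isotropic_columns
    groups = GroupStructure.singletons(Am.shape[1], exempt)
    return solve_group_lasso(Am, y, groups, config)


def lambda_sweep(A, y: np.ndarray, groups: GroupStructure,
                 lambda_grid: np.ndarray, config: SolverConfig | None = None
                 ) -> list[Solution]:
    """One group-lasso solve per ascending lambda, warm-started left to right.

    The NNLS base solve (adaptive-weight denominators) is shared across the
    grid; only the global strength changes.
    """
    config = config or SolverConfig()
    lambda_grid = np.asarray(lambda_grid, float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(lambda_grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    Am = _as_sparse(A)
    base = solve_nnls(Am, y, SolverConfig(max_iter=config.max_iter,
                                          tol=config.tol, seed=config.seed))
    sols: list[Solution] = []
    x_prev: np.ndarray | None = None
    for lam in lambda_grid:
        if lam == 0.0:
            sols.append(base)
            x_prev = base.x
            continue
        wg = compute_adaptive_weights(base.x, groups, float(lam))
        sol = solve_group_lasso(Am, y, wg,
                                SolverConfig(lam=float(lam), max_iter=config.max_iter,
                                             tol=config.tol, seed=config.seed),
                                x0=x_prev)
        sols.append(sol)
        x_prev = sol.x
    return sols


def default_lambda_grid(A, y: np.ndarray, groups: GroupStructure,
                        n_points: int = 20, span: float = 1e-4,
                        config: SolverConfig | None = None) -> np.ndarray:
    """Log-spaced grid ending at the strength that silences every bundle.

    ``lambda_max`` is the smallest global strength at which x = 0 satisfies
    the optimality condition for all penalized groups (using the adaptive
    denominators), computed from the gradient at zero; the grid spans
    ``[span * lambda_max, lambda_max]``.
    """
    config = config or SolverConfig()
    Am = _as_sparse(A)
    base = solve_nnls(Am, y, config)
    g0 = np.maximum(2.0 * (Am.T @ np.asarray(y, float)), 0.0)
    lam_max = 0.0
    for g in groups.groups:
        nrm_nnls = float(np.linalg.norm(base.x[g]))
        if nrm_nnls == 0.0:
            continue
        lam_max = max(lam_max, float(np.linalg.norm(g0[g])) * nrm_nnls / len(g))
    if lam_max == 0.0:
        raise ValueError("no penalizable signal: cannot build a lambda grid")
    return np.geomspace(span * lam_max, lam_max, n_points)


def stationarity_residual(A, y: np.ndarray, x: np.ndarray,
                          groups: GroupStructure | None = None) -> float:
    """Sup-norm of the fixed-point residual ``x - prox(x - grad/L)``.

    Zero exactly at a constrained stationary point; used as the KKT check.
    """
    Am = _as_sparse(A)
    L = 2.0 * spectral_norm_sq(Am) * 1.01
    grad = 2.0 * (Am.T @ (Am @ x - np.asarray(y, float)))
    v = x - grad / L
    if groups is None or groups.weights is None:
        p = np.maximum(v, 0.0)
    else:
        p = group_prox(v, groups, groups.weights / L)
    return float(np.max(np.abs(x - p))) if len(x) else 0.0
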