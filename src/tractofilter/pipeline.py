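"""End-to-end fitting and phantom experiments.

``fit_tractogram`` runs the full filtering chain on one set of inputs:
endpoint assignment, bundle grouping, forward-operator assembly, NNLS for
the adaptive weights, then the group-lasso solve at a chosen strength.
Streamlines that cannot be assigned to a distinct ROI pair are excluded
from the fit (their weight is reported as zero) and counted.

``phantom_experiment`` generates a phantom plus candidate tractogram,
sweeps the regularization strength over a log grid, and scores bundle-aware
filtering against the unregularized fit, lasso, cardinality thresholding
and random bundle removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (BundleGrouping, Connectome, EndpointAssignment,
                         assign_endpoints, build_connectome, group_by_pairs)
from .evaluation import (EvaluationReport, evaluate, random_filter_score,
                         roc_sweep, threshold_sweep)
from .forward import ContributionMatrix, build_matrix
from .grid import Parcellation
from .phantom import Phantom, generate_candidate_tractogram, make_phantom
from .solvers import (GroupStructure, Solution, SolverConfig,
                      default_lambda_grid, lambda_sweep, solve_group_lasso,
                      solve_nnls)
from .tractogram import Tractogram


@dataclass
class FitResult:
    """Outcome of one filtering run on a tractogram."""

    weights: np.ndarray              # per input streamline; 0 for unassigned
    solution: Solution
    assignment: EndpointAssignment
    grouping: BundleGrouping
    matrix: ContributionMatrix
    groups: GroupStructure
    filtered_connectome: Connectome
    raw_connectome: Connectome
    n_unassigned: int

    @property
    def active_pairs(self) -> set[tuple[int, int]]:
        return {self.grouping.pair_list[i] for i in self.solution.active_groups}


def fit_tractogram(tractogram: Tractogram, parcellation: Parcellation,
                   fraction_map: np.ndarray, lam: float = 0.0,
                   radius: float = 2.0,
                   config: SolverConfig | None = None) -> FitResult:
    """Filter a tractogram against an intra-axonal fraction map.

    ``lam = 0`` is the plain NNLS fit; ``lam > 0`` adds the adaptive
    group-lasso penalty over ROI-pair bundles.
    """
    config = config or SolverConfig()
    assignment = assign_endpoints(tractogram, parcellation, radius)
    mask = assignment.assigned
    n_unassigned = int((~mask).sum())
    sub_tract = tractogram.subset(mask)
    if len(sub_tract) == 0:
        raise ValueError("no streamline connects two distinct ROIs; nothing to fit")
    grouping = group_by_pairs(assignment.subset(mask))
    A = build_matrix(sub_tract, parcellation.grid, mode="length")
    groups = grouping.to_group_structure(A.n_columns)
    y = np.asarray(fraction_map, float).ravel(order="F")

    if lam == 0.0:
        sol = solve_nnls(A, y, config)
        norms = np.array([float(np.linalg.norm(sol.x[g])) for g in groups.groups])
        sol.group_norms = norms
        sol.active_groups = [i for i, v in enumerate(norms) if v > 1e-12]
    else:
        sol = solve_group_lasso(A, y, groups,
                                SolverConfig(lam=lam, max_iter=config.max_iter,
                                             tol=config.tol, seed=config.seed))

    weights = np.zeros(len(tractogram))
    weights[np.flatnonzero(mask)] = sol.x
    return FitResult(
        weights=weights, solution=sol, assignment=assignment, grouping=grouping,
        matrix=A, groups=groups,
        filtered_connectome=build_connectome(assignment, weights, "sum_of_weights"),
        raw_connectome=build_connectome(assignment, None, "streamline_count"),
        n_unassigned=n_unassigned)


@dataclass
class PhantomExperiment:
    """A phantom, its candidate tractogram and the full method comparison."""

    phantom: Phantom
    tractogram: Tractogram
    assignment: EndpointAssignment
    lambda_grid: np.ndarray
    solutions: list[Solution]
    group_pairs: list[tuple[int, int]]
    roc: pd.DataFrame                 # bundle-aware sweep
    roc_lasso: pd.DataFrame | None
    threshold_table: pd.DataFrame
    raw_report: EvaluationReport
    P: int
    N: int

    @property
    def best_row(self) -> pd.Series:
        return self.roc.loc[self.roc["J"].idxmax()]

    def active_pairs(self, solution_index: int) -> set[tuple[int, int]]:
        sol = self.solutions[solution_index]
        return {self.group_pairs[i] for i in sol.active_groups}


def phantom_experiment(seed: int = 0, n_rois: int = 12, n_bundles: int = 6,
                       n_false_bundles: int = 6,
                       grid_dims: tuple[int, int, int] = (20, 20, 20),
                       fibers_per_bundle: int = 12,
                       streamlines_per_false_bundle: int = 8,
                       jitter_mm: float = 0.2, n_lambdas: int = 20,
                       lambda_span: float = 1e-4, radius: float = 2.0,
                       run_lasso: bool = False,
                       config: SolverConfig | None = None) -> PhantomExperiment:
    """Generate a phantom, fit the candidate tractogram over a lambda grid
    and score every method against the ground truth.

    P is the number of true bundles; N counts the ROI pairs reachable by
    the splicing mechanism (the negatives tractography could produce).
    """
    config = config or SolverConfig()
    rng = np.random.default_rng(seed)
    phantom = make_phantom(n_rois=n_rois, n_bundles=n_bundles, grid_dims=grid_dims,
                           fibers_per_bundle=fibers_per_bundle,
                           seed=int(rng.integers(2**31 - 1)))
    tract = generate_candidate_tractogram(
        phantom, streamlines_per_true_bundle=fibers_per_bundle,
        n_false_bundles=n_false_bundles,
        streamlines_per_false_bundle=streamlines_per_false_bundle,
        jitter_mm=jitter_mm, seed=int(rng.integers(2**31 - 1)))

    assignment = assign_endpoints(tract, phantom.parcellation, radius)
    mask = assignment.assigned
    sub_tract = tract.subset(mask)
    sub_assign = assignment.subset(mask)
    grouping = group_by_pairs(sub_assign)
    A = build_matrix(sub_tract, phantom.grid, mode="length")
    groups = grouping.to_group_structure(A.n_columns)
    y = phantom.y_vector

    grid = default_lambda_grid(A, y, groups, n_points=n_lambdas,
                               span=lambda_span, config=config)
    sols = lambda_sweep(A, y, groups, grid, config)

    P = len(phantom.true_bundles)
    N = int(tract.meta["n_reachable_negatives"])
    truth = phantom.true_connectome
    roc = roc_sweep(sols, sub_assign, truth, P, N, lambdas=grid)

    roc_lasso = None
    if run_lasso:
        singles = GroupStructure.singletons(A.n_columns)
        sols_l = lambda_sweep(A, y, singles, default_lambda_grid(
            A, y, singles, n_points=n_lambdas, span=lambda_span, config=config),
            config)
        roc_lasso = roc_sweep(sols_l, sub_assign, truth, P, N)

    raw_conn = build_connectome(assignment, None, "streamline_count")
    raw_report = evaluate(raw_conn, truth, P, N)
    thr = threshold_sweep(raw_conn, truth, P, N)

    return PhantomExperiment(
        phantom=phantom, tractogram=tract, assignment=assignment,
        lambda_grid=grid, solutions=sols, group_pairs=grouping.pair_list,
        roc=roc, roc_lasso=roc_lasso, threshold_table=thr,
        raw_report=raw_report, P=P, N=N)


def matched_random_baseline(exp: PhantomExperiment, n_repeats: int = 100,
                            seed: int = 0) -> float:
    """Mean J of random bundle removal at the removal rate of the best
    bundle-aware solution."""
    raw_conn = build_connectome(exp.assignment, None, "streamline_count")
    n_edges_raw = len(raw_conn.edge_set())
    best_idx = int(exp.roc["J"].idxmax())
    n_active = len(exp.solutions[best_idx].active_groups)
    rate = 1.0 - n_active / n_edges_raw if n_edges_raw else 0.0
    return random_filter_score(raw_conn, exp.phantom.true_connectome,
                               exp.P, exp.N, rate, n_repeats, seed)
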