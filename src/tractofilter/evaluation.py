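"""Scoring estimated connectomes against a known ground truth.

Bundles (connectome edges) are classified as valid (present in the ground
truth) or invalid. Sensitivity is VB / P where P is the number of real
positive bundles; specificity is 1 - IB / N where N is the number of real
negatives, i.e. ROI pairs that tractography could incorrectly connect.
Youden's index J = sensitivity + specificity - 1 summarizes both.

Edge-weight accuracy is measured after normalizing each connectome by its
own maximum entry, as the root of the sum of squared differences over the
upper triangle — over all edges (epsilon) or over the true-positive
positions only (epsilon_TP).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .connectome import Connectome, network_density
from .solvers import GroupStructure, Solution


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    scale = 10.0 ** ndigits
    return np.sign(value) * np.floor(abs(value) * scale + 0.5) / scale


@dataclass
class EvaluationReport:
    """Bundle-level classification and weight-accuracy summary."""

    VB: int
    IB: int
    VC: float | None
    IC: float | None
    sensitivity: float
    specificity: float
    youden_J: float
    epsilon: float | None
    epsilon_TP: float | None
    n_positives: int
    n_negatives: int
    network_density: float

    def to_dict(self) -> dict:
        return asdict(self)


def classify_bundles(estimated: Connectome, truth: Connectome
                     ) -> tuple[int, int, float | None, float | None]:
    """(VB, IB, VC, IC): valid/invalid bundle counts and streamline ratios.

    VC and IC (fractions of streamlines landing on valid/invalid edges) are
    reported only when the estimated connectome carries streamline counts.
    """
    if estimated.roi_labels != truth.roi_labels:
        raise ValueError("connectomes have different ROI label sets")
    true_edges = truth.edge_set()
    est_edges = estimated.edge_set()
    vb = len(est_edges & true_edges)
    ib = len(est_edges - true_edges)
    vc = ic = None
    if estimated.weight_definition == "streamline_count":
        total = estimated.matrix.sum() / 2.0
        if total > 0:
            valid = sum(estimated.edge_weight(a, b) for a, b in est_edges & true_edges)
            invalid = sum(estimated.edge_weight(a, b) for a, b in est_edges - true_edges)
            vc, ic = valid / total, invalid / total
    return vb, ib, vc, ic


def youden(VB: int, IB: int, P: int, N: int) -> float:
    """J = VB/P + (1 - IB/N) - 1."""
    if P < 1 or N < 1:
        raise ValueError("P and N must be >= 1")
    if not (0 <= VB <= P):
        raise ValueError(f"VB = {VB} outside [0, P = {P}]")
    if not (0 <= IB <= N):
        raise ValueError(f"IB = {IB} outside [0, N = {N}]")
    return VB / P + (1.0 - IB / N) - 1.0


def sensitivity(VB: int, P: int) -> float:
    return VB / P


def specificity(IB: int, N: int) -> float:
    return 1.0 - IB / N


def connectome_error(estimated: Connectome, truth: Connectome,
                     mode: str = "all", triangle: str = "upper") -> float:
    """Root-sum-squared difference between max-normalized connectomes.

    ``mode="tp_only"`` restricts the sum to ground-truth edge positions.
    ``triangle="full"`` sums the whole symmetric matrix (sqrt(2) times the
    upper-triangle value).
    """
    if estimated.roi_labels != truth.roi_labels:
        raise ValueError("connectomes have different ROI label sets")
    if mode not in ("all", "tp_only"):
        raise ValueError(f"unknown mode {mode!r}")
    t = truth.matrix
    if t.max() <= 0:
        raise ValueError("ground-truth connectome is empty")
    t = t / t.max()
    e = estimated.matrix
    e = e / e.max() if e.max() > 0 else e  # all-zero estimate stays zero
    diff2 = (t - e) ** 2
    r = len(t)
    if triangle == "upper":
        mask = np.triu(np.ones((r, r), bool), k=1)
    elif triangle == "full":
        mask = ~np.eye(r, dtype=bool)
    else:
        raise ValueError(f"unknown triangle {triangle!r}")
    if mode == "tp_only":
        mask &= truth.matrix > 0
    return float(np.sqrt(diff2[mask].sum()))


def evaluate(estimated: Connectome, truth: Connectome, P: int, N: int
             ) -> EvaluationReport:
    """Full report for one estimated connectome against the ground truth."""
    vb, ib, vc, ic = classify_bundles(estimated, truth)
    eps = eps_tp = None
    if truth.matrix.max() > 0:
        eps = connectome_error(estimated, truth, "all")
        eps_tp = connectome_error(estimated, truth, "tp_only")
    return EvaluationReport(VB=vb, IB=ib, VC=vc, IC=ic,
                            sensitivity=sensitivity(vb, P),
                            specificity=specificity(ib, N),
                            youden_J=youden(vb, ib, P, N),
                            epsilon=eps, epsilon_TP=eps_tp,
                            n_positives=P, n_negatives=N,
                            network_density=network_density(estimated))


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def threshold_filter(connectome: Connectome, k: int) -> Connectome:
    """Drop edges whose streamline count is <= k (cardinality thresholding)."""
    if connectome.weight_definition != "streamline_count":
        raise ValueError("thresholding is defined on streamline counts")
    if k < 0:
        raise ValueError("k must be >= 0")
    m = connectome.matrix.copy()
    m[m <= k] = 0.0
    return Connectome(list(connectome.roi_labels), m, "streamline_count")


def threshold_sweep(connectome: Connectome, truth: Connectome, P: int, N: int
                    ) -> pd.DataFrame:
    """J as a function of the cardinality threshold k (one row per k)."""
    counts = sorted({int(v) for v in connectome.matrix[np.triu_indices_from(
        connectome.matrix, k=1)] if v > 0})
    ks = [0] + counts
    rows = []
    for k in ks:
        vb, ib, _, _ = classify_bundles(threshold_filter(connectome, k), truth)
        rows.append({"k": k, "VB": vb, "IB": ib, "J": youden(vb, ib, P, N)})
    return pd.DataFrame(rows)


def random_filter_score(estimated: Connectome, truth: Connectome, P: int, N: int,
                        removal_rate: float, n_repeats: int = 100,
                        seed: int = 0) -> float:
    """Mean J after removing floor(rate * n_bundles) random edges, repeated."""
    if not (0.0 <= removal_rate <= 1.0):
        raise ValueError("removal_rate must be in [0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    edges = sorted(estimated.edge_set())
    n_remove = int(np.floor(removal_rate * len(edges)))
    rng = np.random.default_rng(seed)
    true_edges = truth.edge_set()
    js = np.empty(n_repeats)
    for r in range(n_repeats):
        keep = set(map(tuple, np.asarray(edges)[
            rng.permutation(len(edges))[: len(edges) - n_remove]]))
        vb = len(keep & true_edges)
        ib = len(keep - true_edges)
        js[r] = youden(vb, ib, P, N)
    return float(js.mean())


def roc_sweep(solutions: list[Solution], assignment, truth: Connectome,
              P: int, N: int, lambdas=None) -> pd.DataFrame:
    """Classification metrics per regularization strength.

    Builds a sum-of-weights connectome from each solution's streamline
    weights, classifies it against the truth and tabulates
    (lambda, VB, IB, sensitivity, specificity, J). The last row's ``best``
    column marks the argmax-J entry.
    """
    from .connectome import build_connectome
    if not solutions:
        raise ValueError("no solutions to sweep")
    lambdas = list(lambdas) if lambdas is not None else list(range(len(solutions)))
    rows = []
    for lam, sol in zip(lambdas, solutions):
        weights = sol.x[: len(assignment)]
        conn = build_connectome(assignment, weights, "sum_of_weights")
        vb, ib, _, _ = classify_bundles(conn, truth)
        rows.append({"lambda": lam, "VB": vb, "IB": ib,
                     "sensitivity": sensitivity(vb, P),
                     "specificity": specificity(ib, N),
                     "J": youden(vb, ib, P, N)})
    df = pd.DataFrame(rows)
    df["best"] = False
    df.loc[df["J"].idxmax(), "best"] = True
    return df
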