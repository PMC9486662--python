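"""Permutation-based validation of the terminal discrimination pattern.

The three terminal measures of each impaired subgroup are recombined as a
Cartesian product of the observed values (n patients -> n^3 simulated
triples per subgroup, 343 for n = 7).  Extreme recombinations are discarded
by requiring the squared Mahalanobis distance to the TOR-normal subgroup's
mean — with the TOR-normal sample covariance, unbiased (n-1) estimator — to
lie within the range spanned by the subgroup's original patients.  Accepted
triples are projected onto the salient component to give simulated patient
scores, whose combined distributions yield an ROC curve and its optimal
(Youden) operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .pca_cascade import PCAResult

__all__ = [
    "PermutationSet",
    "ROCResult",
    "enumerate_recombinations",
    "mahalanobis_filter",
    "simulate_scores",
    "roc_analysis",
    "operating_point",
    "build_permutation_set",
]


def enumerate_recombinations(values: np.ndarray) -> np.ndarray:
    """Cartesian product of observed values across the three measures.

    ``values`` is an (n patients x 3 measures) array; the result is an
    (n^3 x 3) array in lexicographic order of patient indices, so the
    original patient triples appear at rows i*(n^2+n+1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("expected an (n x 3) array of measure values")
    n = values.shape[0]
    idx = np.array(list(product(range(n), repeat=3)))
    return np.column_stack([values[idx[:, j], j] for j in range(3)])


def mahalanobis_filter(triples: np.ndarray, tn_reference: np.ndarray,
                       limits: tuple[float, float],
                       squared: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Accept flags and (squared) Mahalanobis distances to the TN mean.

    ``tn_reference`` holds the TOR-normal subgroup's rows in the same three
    measures.  A triple is accepted iff its distance lies inside ``limits``
    (inclusive).  Raises on a numerically singular covariance.
    """
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    ref = np.asarray(tn_reference, dtype=float)
    if ref.shape[0] < 4:
        raise ValueError("need >= 4 TOR-normal rows for an invertible "
                         "3x3 covariance")
    mean = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False, ddof=1)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"TOR-normal covariance is singular (condition number {cond:.3g})")
    inv = np.linalg.inv(cov)
    diff = triples - mean
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    d = d2 if squared else np.sqrt(d2)
    lo, hi = limits
    accept = (d >= lo) & (d <= hi)
    return accept, d


def simulate_scores(triples: np.ndarray, pca: PCAResult,
                    component: int) -> np.ndarray:
    """Project recombined triples onto one component of the fitted PCA.

    The measure order of ``triples`` must match ``pca.measures`` exactly;
    a column-count mismatch raises immediately (order is part of the
    contract and silently wrong orders would corrupt every score).
    """
    proj = pca.project(triples)
    return proj[:, component]


@dataclass
class PermutationSet:
    """Recombined score triples for one subgroup with filter bookkeeping."""

    subgroup: str
    triples: np.ndarray
    distances: np.ndarray
    accepted: np.ndarray
    scores: np.ndarray
    limits: tuple[float, float]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def accepted_scores(self) -> np.ndarray:
        return self.scores[self.accepted]


def build_permutation_set(z_values: np.ndarray, subgroup: str,
                          tn_reference: np.ndarray, pca: PCAResult,
                          component: int,
                          squared: bool = True) -> PermutationSet:
    """Full recombination -> filter -> projection pipeline for one subgroup.

    Acceptance limits are the min/max distances of the subgroup's original
    patients, so every original patient is accepted by construction.
    """
    z_values = np.asarray(z_values, dtype=float)
    triples = enumerate_recombinations(z_values)
    _, orig_d = mahalanobis_filter(z_values, tn_reference, (0.0, np.inf),
                                   squared=squared)
    limits = (float(orig_d.min()), float(orig_d.max()))
    accept, d = mahalanobis_filter(triples, tn_reference, limits,
                                   squared=squared)
    scores = simulate_scores(triples, pca, component)
    return PermutationSet(subgroup=subgroup, triples=triples, distances=d,
                          accepted=accept, scores=scores, limits=limits)


@dataclass
class ROCResult:
    """ROC sweep over score thresholds with the Youden-optimal point."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    youden_j: float
    tpr_at_optimum: float
    fpr_at_optimum: float
    positive_class: str
    balanced_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.balanced_accuracy = float(
            (self.tpr_at_optimum + 1.0 - self.fpr_at_optimum) / 2.0)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "tpr": self.tpr, "fpr": self.fpr})


def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 positive_class: str = "RTI") -> ROCResult:
    """ROC curve for "score >= threshold -> positive" classification.

    Thresholds sweep the unique scores; the optimal operating point
    maximizes Youden's J = TPR - FPR (ties broken toward the smaller FPR);
    AUC is the trapezoidal area under the (FPR, TPR) curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    uniq = np.unique(scores)
    # anchor the sweep at (1, 1) below all scores and (0, 0) above them
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        above = scores >= t
        tpr[i] = (above & pos).sum() / n_pos
        fpr[i] = (above & ~pos).sum() / n_neg
    order = np.lexsort((tpr, fpr))  # by FPR, ties by ascending TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmin(fpr[candidates])]
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     optimal_threshold=float(thresholds[best]),
                     youden_j=float(j[best]),
                     tpr_at_optimum=float(tpr[best]),
                     fpr_at_optimum=float(fpr[best]),
                     positive_class=positive_class)


def operating_point(scores: np.ndarray, labels: np.ndarray, threshold: float,
                    positive_class: str = "RTI") -> tuple[float, float]:
    """(TPR, FPR) of the rule "score >= threshold -> positive"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both classes must be non-empty")
    above = scores >= threshold
    return (float((above & pos).sum() / pos.sum()),
            float((above & ~pos).sum() / (~pos).sum()))


def plot_validation(perm_sets: dict[str, PermutationSet], roc: ROCResult,
                    path) -> None:
    """Score histograms per subgroup and the ROC curve with its optimum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    colors = {"PTI": "tab:red", "RTI": "tab:blue"}
    for name, ps in perm_sets.items():
        axes[0].hist(ps.accepted_scores, bins=25, alpha=0.6,
                     color=colors.get(name, None), label=name)
    axes[0].axvline(roc.optimal_threshold, ls=":", color="k")
    axes[0].set_xlabel("simulated patient score")
    axes[0].set_ylabel("count")
    axes[0].legend()
    axes[1].plot(roc.fpr, roc.tpr, "-", color="k")
    axes[1].plot([roc.fpr_at_optimum], [roc.tpr_at_optimum], "o",
                 color="tab:orange")
    axes[1].plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    axes[1].set_xlabel("false positive rate")
    axes[1].set_ylabel("true positive rate")
    axes[1].set_title(f"AUC = {roc.auc:.3f}, J = {roc.youden_j:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
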