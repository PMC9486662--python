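"""The Occam's-razor cascade of principal component analyses.

Starting from the full set of admission measures, each stage fits a PCA on
the mean-centred z-scores (no re-scaling: the inputs are already
standardized), admits components up to a cumulative explained-variance
threshold (default 80%), scores each admitted component for *salience* —
significant Pearson correlation (p < 0.05) between its patient scores and
the nine-month tactile object recognition outcome — and retains the
measures carrying dominant expression coefficients in the most salient
component.  The cascade recurses on the retained measures until the set
stabilizes or shrinks to three measures; the terminal stage also yields a
patient-score threshold separating recovered from persistently impaired
patients.

Component signs are arbitrary in PCA; they are fixed here so the tactile
object recognition coefficient is non-negative (falling back to the
largest-magnitude coefficient when TOR is absent), which makes recovered
patients score higher than persistently impaired ones.

Dominance is not an established convention; here a measure is dominant
when its absolute coefficient reaches ``dominance_ratio`` (default 0.6)
times the largest absolute coefficient of the salient component.  When a
reduction to three measures discards one of the two geometrical
discrimination tasks (micro vs. macro), both three-measure variants are
fitted and the branch with the stronger Kruskal-Wallis subgroup
discrimination is reported as terminal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral_prep import ZMatrix, assemble_features
from .smallsample_stats import kruskal_wallis

__all__ = [
    "PCAResult",
    "SalientComponent",
    "CascadeStage",
    "CascadeResult",
    "run_pca",
    "select_components",
    "assess_salience",
    "dominant_measures",
    "run_cascade",
]


@dataclass
class PCAResult:
    """Result of one PCA: orthonormal expression coefficients (measures x
    components), patient scores (patients x components), per-component
    variance fractions and the per-measure centring vector."""

    measures: list[str]
    patient_ids: list[str]
    expression_coefficients: np.ndarray
    patient_scores: np.ndarray
    variance_fraction: np.ndarray
    center: np.ndarray
    rank_deficient: bool = False

    @property
    def n_components(self) -> int:
        return self.expression_coefficients.shape[1]

    def project(self, rows: np.ndarray) -> np.ndarray:
        """Project new rows (same measure order) onto the components."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != len(self.measures):
            raise ValueError(
                f"expected {len(self.measures)} measures "
                f"({self.measures}), got {rows.shape[1]} columns")
        return (rows - self.center) @ self.expression_coefficients


def run_pca(z: ZMatrix) -> PCAResult:
    """Principal component analysis of the z-score matrix.

    Mean-centred, un-rescaled; components ordered by decreasing variance
    fraction; variance fractions sum to one.  With fewer observations than
    measures the trailing components carry zero variance and the result is
    flagged rank-deficient.
    """
    x = z.values
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 patients and 2 measures")
    if np.isnan(x).any():
        raise ValueError("z-matrix contains missing values")
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=(n <= m))
    coef = vt.T[:, :m]
    var = np.zeros(m)
    k = min(n, m)
    var[:k] = (s[:k] ** 2) / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.full(m, 1.0 / m)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    # sign convention: TOR coefficient non-negative, else largest coefficient
    tor_idx = None
    for name in ("tor0", "tor"):
        if name in z.measures:
            tor_idx = z.measures.index(name)
            break
    for j in range(coef.shape[1]):
        col = coef[:, j]
        anchor = tor_idx if (tor_idx is not None and abs(col[tor_idx]) > 1e-12) \
            else int(np.argmax(np.abs(col)))
        if col[anchor] < 0:
            coef[:, j] = -col
    scores = xc @ coef
    return PCAResult(measures=list(z.measures),
                     patient_ids=[str(p) for p in z.data.index],
                     expression_coefficients=coef,
                     patient_scores=scores,
                     variance_fraction=frac,
                     center=center,
                     rank_deficient=rank < m)


def select_components(res: PCAResult, cum_threshold: float = 0.8) -> list[int]:
    """Smallest prefix of components with cumulative variance >= threshold."""
    if not 0.0 < cum_threshold <= 1.0:
        raise ValueError("cum_threshold must lie in (0, 1]")
    cum = np.cumsum(res.variance_fraction)
    k = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
    return list(range(min(k, res.n_components)))


@dataclass
class SalientComponent:
    """Salience bookkeeping for one component: outcome correlation,
    Kruskal-Wallis discrimination between subgroups, dominant measures."""

    component: int
    r: float
    p: float
    kw_chi2: float
    kw_p: float
    salient: bool
    dominant: list[str] = field(default_factory=list)


def assess_salience(res: PCAResult, idx: int, tor9: np.ndarray,
                    labels: np.ndarray, alpha: float = 0.05,
                    method: str = "pearson") -> SalientComponent:
    """Score one component for salience.

    Salient iff the correlation between its patient scores and the
    nine-month outcome is significant at ``alpha``.  The Kruskal-Wallis
    statistic quantifies discrimination of the RTI vs PTI patient scores.
    A constant score vector makes the correlation undefined and the
    component non-salient.
    """
    scores = res.patient_scores[:, idx]
    tor9 = np.asarray(tor9, dtype=float)
    labels = np.asarray(labels)
    if len(tor9) != len(scores) or np.isnan(tor9).any():
        raise ValueError("outcome must be present for every patient")
    if np.ptp(scores) < 1e-12 or np.ptp(tor9) < 1e-12:
        return SalientComponent(idx, np.nan, np.nan, 0.0, 1.0, False)
    if method == "pearson":
        r, p = stats.pearsonr(scores, tor9)
    elif method == "spearman":
        r, p = stats.spearmanr(scores, tor9)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    groups = [scores[labels == g] for g in ("RTI", "PTI")]
    if all(len(g) for g in groups):
        kw = kruskal_wallis(groups)
        kw_chi2, kw_p = kw.value, kw.p
    else:
        kw_chi2, kw_p = 0.0, 1.0
    return SalientComponent(idx, float(r), float(p), kw_chi2, kw_p,
                            bool(p < alpha))


def dominant_measures(res: PCAResult, idx: int,
                      dominance_ratio: float = 0.6) -> list[str]:
    """Measures with |coefficient| >= ratio x max |coefficient| on component
    ``idx``.  Returns measures in their current order.  If every measure
    qualifies the cascade cannot shrink further (termination signal handled
    by the caller)."""
    col = np.abs(res.expression_coefficients[:, idx])
    cutoff = dominance_ratio * col.max()
    return [m for m, c in zip(res.measures, col) if c >= cutoff - 1e-12]


@dataclass
class CascadeStage:
    measures: list[str]
    pca: PCAResult
    salient: SalientComponent


@dataclass
class CascadeResult:
    """Ordered stages of the cascade plus the terminal discrimination rule."""

    stages: list[CascadeStage]
    terminal_measures: list[str]
    terminal_threshold: float | None
    inconclusive: bool = False

    @property
    def terminal_stage(self) -> CascadeStage:
        return self.stages[-1]

    def summary_table(self) -> pd.DataFrame:
        """One row per stage: salient component, its expression
        coefficients by measure, and the Kruskal-Wallis discrimination."""
        rows = []
        for stage in self.stages:
            row = {"pca": "PC" + "".join(str(len(stage.measures))),
                   "salient_component": stage.salient.component + 1,
                   "r_tor9": stage.salient.r, "p_tor9": stage.salient.p,
                   "kw_chi2": stage.salient.kw_chi2,
                   "kw_p": stage.salient.kw_p}
            coefs = stage.pca.expression_coefficients[:, stage.salient.component]
            for m, c in zip(stage.measures, coefs):
                row[m] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terminal_measures": self.terminal_measures,
            "terminal_threshold": self.terminal_threshold,
            "inconclusive": self.inconclusive,
            "stages": [
                {
                    "measures": st.measures,
                    "variance_fraction": st.pca.variance_fraction.tolist(),
                    "expression_coefficients":
                        st.pca.expression_coefficients.tolist(),
                    "center": st.pca.center.tolist(),
                    "patient_scores": st.pca.patient_scores.tolist(),
                    "salient": {
                        "component": st.salient.component,
                        "r": st.salient.r, "p": st.salient.p,
                        "kw_chi2": st.salient.kw_chi2,
                        "kw_p": st.salient.kw_p,
                        "dominant": st.salient.dominant,
                    },
                }
                for st in self.stages
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _best_salient(res: PCAResult, admitted: list[int], tor9, labels,
                  alpha: float, method: str) -> SalientComponent | None:
    """Among admitted components, the salient one that best discriminates.

    Salience is the outcome-correlation gate (p < alpha); when several
    admitted components pass it, the one whose patient scores discriminate
    the subgroups most strongly (largest Kruskal-Wallis chi-square) carries
    the stage, discrimination being the purpose of the cascade.
    """
    assessments = [assess_salience(res, j, tor9, labels, alpha, method)
                   for j in admitted]
    salient = [a for a in assessments if a.salient]
    if not salient:
        return None
    return max(salient, key=lambda a: (a.kw_chi2, -a.p))


def _discrimination_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Patient-score threshold separating RTI (above) from PTI (below).

    With perfectly separated groups: the midpoint of the gap; otherwise the
    threshold maximizing Youden's J on the original patient scores."""
    rti = scores[labels == "RTI"]
    pti = scores[labels == "PTI"]
    if pti.max() < rti.min():
        return float((pti.max() + rti.min()) / 2.0)
    from .permutation_validation import roc_analysis
    roc = roc_analysis(scores, labels, positive_class="RTI")
    return float(roc.optimal_threshold)


def run_cascade(z: ZMatrix, tor9: np.ndarray, labels: np.ndarray,
                cum_threshold: float = 0.8, dominance_ratio: float = 0.6,
                alpha: float = 0.05, corr_method: str = "pearson",
                min_measures: int = 3) -> CascadeResult:
    """Run the full Occam's-razor cascade.

    ``tor9`` is the nine-month tactile object recognition count (affected
    hand) per patient; ``labels`` the subgroup labels.  Stops when the
    measure set stabilizes or reaches ``min_measures``; flags the result
    inconclusive if a stage has no salient component.
    """
    tor9 = np.asarray(tor9, dtype=float)
    labels = np.asarray(labels)
    current = list(z.measures)
    stages: list[CascadeStage] = []
    while True:
        sub = assemble_features(z, current)
        res = run_pca(sub)
        admitted = select_components(res, cum_threshold)
        assessments = [assess_salience(res, j, tor9, labels, alpha,
                                       corr_method) for j in admitted]
        salient = [a for a in assessments if a.salient]
        if not salient:
            return CascadeResult(stages=stages, terminal_measures=current,
                                 terminal_threshold=None, inconclusive=True)
        # the stage is carried by the salient component that best
        # discriminates the subgroups; retention pools the dominant
        # measures of every admitted salient component
        best = max(salient, key=lambda a: (a.kw_chi2, -a.p))
        retained: list[str] = []
        for a in salient:
            for m in dominant_measures(res, a.component, dominance_ratio):
                if m not in retained:
                    retained.append(m)
        retained = [m for m in current if m in retained]
        best.dominant = dominant_measures(res, best.component,
                                          dominance_ratio)
        stages.append(CascadeStage(measures=current, pca=res, salient=best))
        if len(current) <= min_measures:
            break
        nxt = retained
        salient_comps = [a.component for a in salient]
        if len(nxt) >= len(current):
            # dominance fails to shrink the set: drive on with the
            # best-supported three measures rather than stalling
            nxt = _pad_to_min(res, salient_comps, min_measures)
        if len(nxt) < min_measures:
            nxt = _pad_to_min(res, salient_comps, min_measures)
        # geometrical-discrimination branch: micro- and macrogeometrical
        # discrimination probe one construct at two spatial scales, so a
        # three-measure pattern admits at most one of them; candidate
        # variants swap one for the other (or for the next-dominant
        # measure) and the branch with the best subgroup discrimination
        # is retained
        if len(nxt) == min_measures and {"mic0", "mac0"} & set(nxt):
            current = _resolve_geometry_branch(z, res, best.component, nxt,
                                               tor9, labels, cum_threshold,
                                               alpha, corr_method)
        else:
            current = nxt
    last = stages[-1]
    threshold = _discrimination_threshold(
        last.pca.patient_scores[:, last.salient.component], labels)
    return CascadeResult(stages=stages, terminal_measures=last.measures,
                         terminal_threshold=threshold)


def _pad_to_min(res: PCAResult, salient_comps: list[int],
                min_measures: int) -> list[str]:
    """Top measures by expression coefficient pooled over the salient
    components (each component is unit-norm, so coefficients are directly
    comparable across components)."""
    pooled = np.max(
        np.abs(res.expression_coefficients[:, salient_comps]), axis=1)
    order = np.argsort(pooled)[::-1][:min_measures]
    keep = sorted(order)
    return [res.measures[i] for i in keep]


def _resolve_geometry_branch(z: ZMatrix, res: PCAResult, comp: int,
                             nxt: list[str], tor9, labels,
                             cum_threshold, alpha, corr_method) -> list[str]:
    """Candidate three-measure sets with at most one geometry task each."""
    pair = ("mac0", "mic0")
    present = [m for m in pair if m in nxt]
    candidates: list[list[str]] = []

    def add(cand: list[str]) -> None:
        if sorted(cand) not in [sorted(c) for c in candidates]:
            candidates.append(list(cand))

    if len(present) == 2:
        # both geometry tasks made the cut: replace either with the
        # next-dominant non-geometry measure; macro-variant listed first
        # so that at equal discrimination the shape task (the construct
        # closest to haptic object recognition) is preferred
        col = np.abs(res.expression_coefficients[:, comp])
        ranked = [m for _, m in sorted(zip(col, res.measures), reverse=True)]
        filler = next((m for m in ranked if m not in nxt and m not in pair),
                      None)
        if filler is None:
            return nxt
        add([m if m != "mic0" else filler for m in nxt])
        add([m if m != "mac0" else filler for m in nxt])
    else:
        keep = present[0]
        other = "mic0" if keep == "mac0" else "mac0"
        variants = [list(nxt), [m if m != keep else other for m in nxt]]
        if keep == "mic0":
            variants.reverse()
        for v in variants:
            add(v)
    best_set, best_chi2 = list(nxt), -np.inf
    for cand in candidates:
        sub = assemble_features(z, cand)
        fit = run_pca(sub)
        admitted = select_components(fit, cum_threshold)
        sal = _best_salient(fit, admitted, tor9, labels, alpha, corr_method)
        chi2 = sal.kw_chi2 if sal is not None else -np.inf
        if chi2 > best_chi2 + 1e-9:
            best_set, best_chi2 = cand, chi2
    return best_set
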