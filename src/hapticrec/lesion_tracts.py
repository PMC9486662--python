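"""Lesion-mask analytics: conjunction maps, tract disconnection metrics,
disconnectome maps and voxelwise Liebermeister lesion-behavior mapping.

Disconnection follows the atlas-based convention: for a given lesion and
probabilistic tract map, the *probability* of disconnection is the maximum
tract-probability value under the lesion ("the most overlapped voxel"), a
probability above 0.5 indicating disconnection; the *proportion* is the
lesioned fraction of the tract's voxel extent and reflects the damage to
the tract as a whole.  The disconnectome aggregates per-control visitation
maps: each healthy control whose (binarized) tract territory intersects the
lesion votes for its entire territory, and the map value is the fraction of
controls voting at a voxel.

Voxel-behavior mapping tests, inside a region of interest, every voxel
lesioned in at least two patients with the Liebermeister quasi-exact
measure, and controls the family-wise error by the permutation distribution
of the maximum z over label shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .smallsample_stats import GroupSummary, anova_from_summary, bonferroni, \
    t_from_summary
from .volumes import LesionMask, TractAtlas, check_same_grid

__all__ = [
    "ConjunctionMap",
    "DisconnectionSummary",
    "conjunction_map",
    "smooth_mask",
    "disconnection_metrics",
    "disconnectome_map",
    "vlsm_liebermeister",
    "group_tract_table",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ConjunctionMap:
    """Voxelwise lesion overlap counts with a fraction-of-patients cutoff."""

    counts: np.ndarray
    n_patients: int
    fraction: float
    threshold_patients: int
    conjunction: np.ndarray  # counts >= threshold_patients


def conjunction_map(masks: list[LesionMask], fraction: float) -> ConjunctionMap:
    """Voxels lesioned in at least ``ceil(fraction * n)`` patients.

    A fraction of 0.714 over 21 patients requires 15 overlapping lesions.
    """
    if not masks:
        raise ValueError("no masks given")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    check_same_grid(*[m.data for m in masks])
    counts = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        counts += m.data.astype(np.int32)
    n = len(masks)
    thr = int(np.ceil(fraction * n - 1e-9))
    return ConjunctionMap(counts=counts, n_patients=n, fraction=fraction,
                          threshold_patients=thr,
                          conjunction=counts >= thr)


def smooth_mask(mask: LesionMask, fwhm_mm: float) -> np.ndarray:
    """Gaussian-smooth a binary mask (FWHM in mm); mass-conserving."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    data = mask.data.astype(float)
    if fwhm_mm == 0:
        return data
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / mask.voxel_size_mm
    out = gaussian_filter(data, sigma=sigma_vox, mode="constant")
    return np.clip(out, 0.0, 1.0)


@dataclass
class DisconnectionSummary:
    """Per patient x tract disconnection metrics."""

    patient_id: str
    tract: str
    probability: float
    proportion: float

    @property
    def disconnected(self) -> bool:
        return self.probability > 0.5


def disconnection_metrics(lesion: LesionMask, tract_prob: np.ndarray,
                          tract_name: str = "",
                          tract_mask_threshold: float = 0.0,
                          ) -> DisconnectionSummary:
    """Disconnection probability and proportion of one tract for one lesion.

    ``tract_mask_threshold`` sets the tract-extent cutoff for the proportion
    denominator (default: every voxel with positive probability).
    """
    check_same_grid(lesion.data, tract_prob)
    tract_mask = tract_prob > tract_mask_threshold
    n_tract = int(tract_mask.sum())
    if n_tract == 0:
        raise ValueError(f"tract {tract_name!r} is empty at threshold "
                         f"{tract_mask_threshold}")
    under = tract_prob[lesion.data]
    probability = float(under.max()) if under.size else 0.0
    proportion = float((lesion.data & tract_mask).sum() / n_tract)
    return DisconnectionSummary(patient_id=lesion.patient_id,
                                tract=tract_name, probability=probability,
                                proportion=proportion)


def disconnectome_map(visitation_maps: list[np.ndarray],
                      lesion: "LesionMask | np.ndarray",
                      binarize_fraction: float = 0.5) -> np.ndarray:
    """Disconnection-probability map from per-control visitation maps.

    Each control's visitation map is binarized at ``binarize_fraction`` of
    its own maximum; a control whose territory intersects the lesion marks
    that whole territory as disconnected.  The returned map holds, per
    voxel, the fraction of controls marking it — the probability that the
    lesion disconnects fibres passing there, given inter-individual
    variability of tract geometry.
    """
    if not visitation_maps:
        raise ValueError("need at least one control visitation map")
    data = lesion.data if isinstance(lesion, LesionMask) else \
        np.asarray(lesion).astype(bool)
    check_same_grid(data, *visitation_maps)
    acc = np.zeros(data.shape, dtype=float)
    for vm in visitation_maps:
        peak = float(np.max(vm))
        if peak <= 0:
            continue
        territory = vm >= binarize_fraction * peak
        if (territory & data).any():
            acc += territory
    return acc / len(visitation_maps)


def _liebermeister_z_table(n_patients: int, n_impaired: int) -> np.ndarray:
    """Lookup z[k, a]: k lesioned patients of whom a impaired.

    z is the normal quantile of the one-sided Liebermeister p toward
    positive lesion-impairment association (concordant cells incremented)."""
    n = n_patients
    table = np.full((n + 1, n + 1), -np.inf)
    for k in range(n + 1):
        a = np.arange(k + 1)
        p = stats.hypergeom.sf(a, n + 2, n_impaired + 1, k + 1)
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
        table[k, :k + 1] = stats.norm.isf(p)
    return table


@dataclass
class VLSMResult:
    z_map: np.ndarray
    threshold: float
    n_tested: int
    n_excluded: int
    suprathreshold: np.ndarray
    max_z_null: np.ndarray


def vlsm_liebermeister(masks: list[LesionMask], outcome: np.ndarray,
                       roi_mask: np.ndarray | None = None,
                       n_permutations: int = 1000, alpha: float = 0.05,
                       min_lesioned: int = 2,
                       fixed_z_threshold: float | None = None,
                       rng: np.random.Generator | None = None) -> VLSMResult:
    """Voxelwise Liebermeister lesion-behavior mapping with permutation FWE.

    ``outcome`` is a binary per-patient vector (1 = impaired).  Voxels are
    tested only inside ``roi_mask`` and only when lesioned in at least
    ``min_lesioned`` (and at most n - 1) patients; z maps the one-sided
    Liebermeister p toward a positive lesion-impairment association.  The
    family-wise threshold is the (1 - alpha) quantile of the maximum-z
    distribution over outcome-label permutations; passing
    ``fixed_z_threshold`` (e.g. 3.98) skips the permutations.
    """
    outcome = np.asarray(outcome).astype(int)
    n = len(masks)
    if outcome.shape != (n,):
        raise ValueError("one outcome per patient required")
    if outcome.sum() < 2 or (1 - outcome).sum() < 2:
        raise ValueError("need >= 2 patients per outcome class")
    check_same_grid(*[m.data for m in masks])
    shape = masks[0].shape
    stack = np.stack([m.data.reshape(-1) for m in masks])  # n x voxels
    lesion_count = stack.sum(axis=0)
    testable = (lesion_count >= min_lesioned) & (lesion_count <= n - 1)
    if roi_mask is not None:
        check_same_grid(roi_mask, shape)
        testable &= roi_mask.reshape(-1).astype(bool)
    n_excluded = int(((lesion_count > 0) & ~testable).sum())
    cols = np.flatnonzero(testable)
    sub = stack[:, cols]                      # n x tested
    k = sub.sum(axis=0)                       # lesioned count per voxel
    ztab = _liebermeister_z_table(n, int(outcome.sum()))

    def z_for(labels: np.ndarray) -> np.ndarray:
        a = labels @ sub                      # lesioned & impaired per voxel
        return ztab[k, a]

    z_vals = z_for(outcome)
    if fixed_z_threshold is not None:
        threshold = float(fixed_z_threshold)
        max_null = np.empty(0)
    else:
        gen = rng or np.random.default_rng(0)
        max_null = np.empty(n_permutations)
        labels = outcome.copy()
        for i in range(n_permutations):
            gen.shuffle(labels)
            zi = z_for(labels)
            max_null[i] = zi.max() if zi.size else -np.inf
        threshold = float(np.quantile(max_null, 1.0 - alpha)) \
            if max_null.size else np.inf
    z_map = np.full(np.prod(shape), np.nan)
    z_map[cols] = z_vals
    z_map = z_map.reshape(shape)
    supra = np.zeros(shape, dtype=bool)
    supra.reshape(-1)[cols] = z_vals > threshold
    return VLSMResult(z_map=z_map, threshold=threshold, n_tested=cols.size,
                      n_excluded=n_excluded, suprathreshold=supra,
                      max_z_null=max_null)


def group_tract_table(summaries: list[DisconnectionSummary],
                      labels: dict[str, str],
                      groups: tuple[str, ...] = ("PTI", "RTI", "TN"),
                      ) -> pd.DataFrame:
    """Group-level tract report: mean (SD) proportion and max probability
    per subgroup, pairwise pooled t-tests (Bonferroni within each tract)
    and a one-way ANOVA of the proportions.

    ``labels`` maps patient ids to subgroup labels.
    """
    df = pd.DataFrame([{"patient_id": s.patient_id, "tract": s.tract,
                        "probability": s.probability,
                        "proportion": s.proportion} for s in summaries])
    df["subgroup"] = df["patient_id"].map(labels)
    present = [g for g in groups if g in set(df["subgroup"])]
    if len(present) < 2:
        raise ValueError("need at least two subgroups")
    rows = []
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    for tract, sub in df.groupby("tract", sort=False):
        row: dict = {"tract": tract}
        gsums = {}
        for g in present:
            vals = sub.loc[sub.subgroup == g, "proportion"]
            gsums[g] = GroupSummary.from_values(g, vals.to_numpy())
            row[f"{g}_mean"] = float(vals.mean())
            row[f"{g}_sd"] = float(vals.std(ddof=1))
            row[f"{g}_maxP"] = float(
                sub.loc[sub.subgroup == g, "probability"].max())
        raw_p = []
        for a, b in pairs:
            try:
                res = t_from_summary(gsums[a], gsums[b])
                row[f"t_{a}_vs_{b}"] = res.value
                raw_p.append(res.p)
            except ValueError:  # both groups constant
                row[f"t_{a}_vs_{b}"] = 0.0
                raw_p.append(1.0)
        for (a, b), p in zip(pairs, bonferroni(raw_p)):
            row[f"p_{a}_vs_{b}"] = p
        anova = anova_from_summary(list(gsums.values()))
        row["anova_F"], row["anova_p"] = anova.value, anova.p
        rows.append(row)
    return pd.DataFrame(rows)
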