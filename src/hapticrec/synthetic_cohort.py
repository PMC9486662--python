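"""Synthetic cohort generator.

Emulates every input of the analysis pipeline so that the full procedure is
exercisable without any patient data download:

* behavioral score tables for three stroke subgroups — persistent tactile
  object recognition impairment (PTI), recovered impairment (RTI) and
  TOR-normal (TN) — whose per-subgroup sample medians fall inside the
  published group ranges;
* a healthy-control reference (per measure x gender x hand mean/SD) for
  z-scoring;
* a toy probabilistic tract atlas (anterior arcuate fasciculus, SLF III,
  corpus callosum) plus binary lesion masks whose fractional overlap with
  the anterior arcuate tract matches the published subgroup moments;
* per-control tract visitation maps for disconnectome construction;
* tactile matching-task count tables (four hand sequences x three visits).

Score marginals are split truncated normals (median = location, range =
truncation bounds, mass concentrated around the median).  A Gaussian copula
couples the measures within each patient through two latent factors:
sensori-motor severity ``s`` (dominant in the timed picking-small-objects
test, pressure threshold and clinical scores) and tactile-discrimination
deficit ``v`` (dominant in shape discrimination and object recognition,
weak in texture discrimination, slightly opposed in the timed motor test,
and driving the nine-month outcome within subgroups).  Together with the
subgroup shifts of the published group tables this plants the structure
the PCA cascade targets: a large severity axis that separates the outcome
groups only weakly, and an outcome-linked discrimination direction that
separates persistent from recovered patients.

All generators are deterministic given ``config.seed``; independent seed
streams are spawned per product so that, e.g., changing the number of
controls does not perturb the patient table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .config import SUBGROUPS, CohortConfig
from .volumes import LesionMask, TractAtlas, check_same_grid

__all__ = [
    "ControlReference",
    "generate_behavioral_cohort",
    "generate_control_reference",
    "toy_tract_atlas",
    "generate_lesion_cohort",
    "generate_visitation_maps",
    "generate_matching_tables",
    "split_truncnorm_ppf",
]

#: measures where a larger raw value means worse performance
LARGER_IS_WORSE = {"pso0", "ppt0", "nih", "lesvol"}
#: measures mapped through the healthy-control reference
CONTROL_MEASURES = ("ppt0", "mic0", "mac0", "pso0", "tor0")
COUNT_MEASURES = {"tor0", "tor3", "tor9"}

_STREAMS = ("behavior", "controls", "lesions", "visitation", "matching")


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


def split_truncnorm_ppf(q, median: float, lo: float, hi: float,
                        spread: float = 2.0):
    """Quantile function of a split truncated normal.

    Each half is a normal centred on the median, truncated to its half-range
    and carrying half of the probability mass, so the distribution's median
    equals ``median`` exactly and its support is [lo, hi].  ``spread``
    expresses the half-range in SDs of the half-normal (2 places the bounds
    at two sigma).  Degenerate halves (median at a bound) put their whole
    mass on the bound.
    """
    q = np.asarray(q, dtype=float)
    out = np.full(q.shape, float(median))
    width = hi - lo
    lower = q < 0.5
    if median > lo:
        scale = (median - lo) / spread
        a = (lo - median) / scale
        out[lower] = stats.truncnorm.ppf(2.0 * q[lower], a, 0.0,
                                         loc=median, scale=scale)
    elif width > 0:
        # median at the floor: half the mass hugs the bound in a narrow
        # band so that ranks (and hence the planted correlation structure)
        # survive instead of collapsing into exact ties
        band = 0.02 * width
        out[lower] = lo + band * stats.truncnorm.ppf(
            2.0 * q[lower], 0.0, 2.0, loc=0.0, scale=0.5)
    else:
        out[lower] = lo
    upper = ~lower
    if hi > median:
        scale = (hi - median) / spread
        b = (hi - median) / scale
        out[upper] = stats.truncnorm.ppf(2.0 * q[upper] - 1.0, 0.0, b,
                                         loc=median, scale=scale)
    elif width > 0:
        band = 0.02 * width
        out[upper] = hi - band * stats.truncnorm.ppf(
            2.0 * (1.0 - q[upper]), 0.0, 2.0, loc=0.0, scale=0.5)
    else:
        out[upper] = hi
    return out


def _patient_ids(group: str, n: int) -> list[str]:
    return [f"{group}{i + 1:02d}" for i in range(n)]


def generate_behavioral_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the per-patient behavioral score table.

    Returns a DataFrame with one row per patient: identifiers (patient_id,
    subgroup, gender, affected_side, plegic flag), clinical measures (age,
    lesion volume in cc, NIHSS) and behavioral scores at admission plus TOR
    at 3 and 9 months.  Plegic patients have missing PSO at admission.  The
    latent factors used by the copula are stored in ``DataFrame.attrs``
    under ``"latents"`` for property testing.
    """
    rng = _rng(config, "behavior")
    rows = []
    latents = []
    for group in config.groups_present():
        n = config.n_per_group[group]
        params = config.score_params[group]
        s = rng.standard_normal(n)
        v = rng.standard_normal(n)
        n_male = int(round(config.male_fraction.get(group, 0.5) * n))
        genders = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(genders)
        # majority of lesions sit in the right hemisphere -> left hand affected
        sides = rng.choice(["L", "R"], size=n, p=[0.6, 0.4])
        values: dict[str, np.ndarray] = {}
        for measure, (med, lo, hi) in params.items():
            a, b = config.factor_loadings.get(measure, (0.0, 0.0))
            c = np.sqrt(max(1.0 - a * a - b * b, 0.0))
            t = a * s + b * v + c * rng.standard_normal(n)
            q = stats.norm.cdf(t)
            if measure not in LARGER_IS_WORSE:
                # larger raw = better, so high latent impairment maps low
                q = 1.0 - q
            spread = config.marginal_spread_overrides.get(
                measure, config.marginal_spread)
            raw = split_truncnorm_ppf(q, med, lo, hi, spread=spread)
            if measure in COUNT_MEASURES:
                raw = np.clip(np.round(raw), lo, hi)
            values[measure] = raw
        # plegic fingers: the most severely impaired patients cannot perform
        # the timed picking-small-objects test at admission
        plegic = np.zeros(n, dtype=bool)
        k = min(config.n_plegic.get(group, 0), n)
        if k > 0:
            plegic[np.argsort(s)[::-1][:k]] = True
        pso = values.get("pso0", np.full(n, np.nan)).copy()
        pso[plegic] = np.nan
        for i, pid in enumerate(_patient_ids(group, n)):
            row = {"patient_id": pid, "subgroup": group,
                   "gender": genders[i], "affected_side": sides[i],
                   "plegic": bool(plegic[i])}
            for measure in params:
                row[measure] = float(values[measure][i])
            row["pso0"] = float(pso[i]) if np.isfinite(pso[i]) else np.nan
            rows.append(row)
            latents.append({"patient_id": pid, "s": float(s[i]),
                            "v": float(v[i])})
    table = pd.DataFrame(rows)
    _check_bounds(table, config)
    table.attrs["latents"] = pd.DataFrame(latents)
    return table


def _check_bounds(table: pd.DataFrame, config: CohortConfig) -> None:
    for group in config.groups_present():
        sub = table[table.subgroup == group]
        for measure, (med, lo, hi) in config.score_params[group].items():
            vals = sub[measure].dropna()
            if len(vals) == 0:
                continue
            if vals.min() < lo - 1e-9 or vals.max() > hi + 1e-9:
                raise RuntimeError(
                    f"{group}/{measure}: generated values escape [{lo}, {hi}]")


@dataclass
class ControlReference:
    """Healthy-control normalization reference.

    ``cells`` is indexed by (measure, gender, hand) with columns ``mean``,
    ``sd`` and ``scale``; the pressure perception threshold is referenced on
    the log10 scale because monofilaments are graded logarithmically.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.cells["sd"] <= 0).any():
            bad = self.cells[self.cells["sd"] <= 0].index.tolist()
            raise ValueError(f"non-positive control SD in cells {bad}")

    def lookup(self, measure: str, gender: str, hand: str) -> tuple[float, float, str]:
        try:
            row = self.cells.loc[(measure, gender, hand)]
        except KeyError as exc:
            raise KeyError(
                f"missing control reference cell ({measure}, {gender}, {hand})"
            ) from exc
        return float(row["mean"]), float(row["sd"]), str(row["scale"])

    def save(self, path) -> None:
        self.cells.reset_index().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "ControlReference":
        df = pd.read_csv(path).set_index(["measure", "gender", "hand"])
        return cls(cells=df)


def generate_control_reference(config: CohortConfig) -> ControlReference:
    """Simulate healthy controls and summarize them per measure/gender/hand.

    Each control contributes both hands; the non-dominant hand is slightly
    slower on the timed test and marginally weaker on object recognition.
    With fewer than two controls of a gender, the cell falls back to the
    whole control sample so that every SD stays strictly positive.
    """
    rng = _rng(config, "controls")
    n = config.n_controls
    n_male = max(n // 2, 1) if n >= 2 else n
    genders = np.array(["M"] * n_male + ["F"] * (n - n_male))
    hand_offsets = {"pso0": {"dom": 0.0, "nondom": 0.8},
                    "tor0": {"dom": 0.0, "nondom": -0.2}}
    gender_offsets = {"ppt0": {"M": 0.02, "F": -0.02}}
    records = []
    raw: dict[tuple[str, str], np.ndarray] = {}
    for measure, (mean, sd, lo, hi) in config.control_params.items():
        for hand in ("L", "R"):
            # right hand dominant for the (majority right-handed) controls
            role = "dom" if hand == "R" else "nondom"
            off = hand_offsets.get(measure, {}).get(role, 0.0)
            goff = np.array([gender_offsets.get(measure, {}).get(g, 0.0)
                             for g in genders])
            a = (lo - (mean + off)) / sd
            b = (hi - (mean + off)) / sd
            vals = stats.truncnorm.rvs(a, b, loc=mean + off, scale=sd,
                                       size=n, random_state=rng) + goff
            vals = np.clip(vals, lo, hi)
            if measure in COUNT_MEASURES:
                vals = np.round(vals)
            raw[(measure, hand)] = vals
    for measure in config.control_params:
        scale = "log10" if measure == "ppt0" else "linear"
        for gender in ("M", "F"):
            sel = genders == gender
            if sel.sum() < 2:
                sel = np.ones(n, dtype=bool)
            for hand in ("L", "R"):
                vals = raw[(measure, hand)][sel]
                sd_val = float(np.std(vals, ddof=1))
                if sd_val <= 0:
                    sd_val = float(config.control_params[measure][1]) * 0.1
                records.append({"measure": measure, "gender": gender,
                                "hand": hand, "mean": float(np.mean(vals)),
                                "sd": sd_val, "scale": scale})
    cells = pd.DataFrame(records).set_index(["measure", "gender", "hand"])
    return ControlReference(cells=cells)


# ---------------------------------------------------------------------------
# toy tract atlas and lesion synthesis
# ---------------------------------------------------------------------------

def _bezier(p0, p1, p2, n=200):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2 * np.asarray(p0) + 2 * (1 - t) * t * np.asarray(p1)
            + t ** 2 * np.asarray(p2))


def _tube(grid_shape, curve_rel, radius_vox):
    """Probabilistic tube around a relative-coordinate Bezier curve."""
    shape = np.asarray(grid_shape, dtype=float)
    pts = _bezier(*[np.asarray(p) * shape for p in curve_rel])
    tree = cKDTree(pts)
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    d, _ = tree.query(idx, k=1)
    sigma = radius_vox / 1.5
    prob = np.exp(-0.5 * (d / sigma) ** 2)
    prob[d > 2.5 * sigma] = 0.0
    prob /= prob.max()  # atlas convention: the tract core has probability 1
    return prob.reshape(grid_shape)


def _sphere(grid_shape, center_rel, radius_vox):
    shape = np.asarray(grid_shape, dtype=float)
    center = np.asarray(center_rel) * shape
    idx = np.indices(grid_shape).astype(float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius_vox ** 2


def toy_tract_atlas(config: CohortConfig) -> TractAtlas:
    """Build the toy tract atlas on the configured grid.

    Three tubular tracts: the anterior arcuate fasciculus (AAF) arcs through
    the right hemisphere between toy frontal and parietal territories, the
    SLF III runs parallel and interlaces with it (sharing roughly a third of
    its voxels), and the corpus callosum crosses the midline.  Cortical
    patches mark the toy parietal subareas PFt and OP1 (lesion core of the
    persistently impaired) and the central Area 4p (core shared by all
    subgroups).
    """
    gs = config.grid_shape
    aaf = _tube(gs, [(0.72, 0.30, 0.52), (0.82, 0.50, 0.74), (0.70, 0.70, 0.50)],
                radius_vox=2.4)
    slf3 = _tube(gs, [(0.80, 0.26, 0.46), (0.88, 0.50, 0.66), (0.78, 0.74, 0.44)],
                 radius_vox=2.4)
    cc = _tube(gs, [(0.25, 0.55, 0.58), (0.50, 0.55, 0.66), (0.75, 0.55, 0.58)],
               radius_vox=2.0)
    patches = {
        "PFt": _sphere(gs, (0.70, 0.74, 0.56), 2.5),
        "OP1": _sphere(gs, (0.72, 0.66, 0.42), 2.5),
        "Area4p": _sphere(gs, (0.66, 0.48, 0.64), 2.5),
    }
    return TractAtlas(tracts={"anterior_arcuate": aaf, "slf3": slf3,
                              "corpus_callosum": cc},
                      voxel_size_mm=config.voxel_size_mm, patches=patches)


def generate_lesion_cohort(config: CohortConfig, atlas: TractAtlas,
                           tolerance: float = 0.02) -> list[LesionMask]:
    """Synthesize one binary lesion mask per patient.

    Per subgroup, fractional-overlap targets with the toy anterior arcuate
    tract are drawn from a truncated normal around the configured
    (mean, SD), then recentred so the subgroup sample mean equals the
    configured mean; each mask is built by claiming the target number of
    tract voxels around a random seed point on the tract, so the achieved
    overlap is exact to one voxel (well inside ``tolerance``).  Cortical
    patch territory (PFt/OP1 for PTI, Area 4p for all groups) and a dilated
    rim are added outside the tract so the overlap fraction is untouched.
    """
    check_same_grid(atlas.shape, config.grid_shape)
    rng = _rng(config, "lesions")
    tract = atlas.tracts["anterior_arcuate"]
    tract_idx = np.argwhere(tract > 0)
    n_tract = len(tract_idx)
    tract_set = tract > 0
    masks: list[LesionMask] = []
    for group in config.groups_present():
        n = config.n_per_group[group]
        mean, sd = config.tract_overlap_params[group]
        if sd > 0:
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            targets = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                          random_state=rng)
            targets = np.clip(targets - (targets.mean() - mean), 0.0, 1.0)
        else:
            targets = np.full(n, mean)
        for i, pid in enumerate(_patient_ids(group, n)):
            n_target = int(round(targets[i] * n_tract))
            lesion = np.zeros(config.grid_shape, dtype=bool)
            if n_target > 0:
                weights = tract[tuple(tract_idx.T)]
                seed_pos = tract_idx[rng.choice(n_tract,
                                                p=weights / weights.sum())]
                d = np.linalg.norm(tract_idx - seed_pos, axis=1)
                d = d + rng.uniform(0.0, 1e-6, size=n_tract)  # tie break
                chosen = tract_idx[np.argsort(d)[:n_target]]
                lesion[tuple(chosen.T)] = True
                rim = binary_dilation(lesion) & ~tract_set
                keep = rng.random(rim.sum()) < 0.6
                rim_idx = np.argwhere(rim)[keep]
                lesion[tuple(rim_idx.T)] = True
            if group == "PTI":
                lesion |= atlas.patches["PFt"] & ~tract_set
                lesion |= atlas.patches["OP1"] & ~tract_set
            lesion |= atlas.patches["Area4p"] & ~tract_set
            achieved = (lesion & tract_set).sum() / n_tract
            if abs(achieved - targets[i]) > tolerance:
                raise RuntimeError(
                    f"{pid}: achieved overlap {achieved:.3f} misses target "
                    f"{targets[i]:.3f} by more than {tolerance}")
            masks.append(LesionMask(data=lesion,
                                    voxel_size_mm=config.voxel_size_mm,
                                    patient_id=pid))
    return masks


def generate_visitation_maps(config: CohortConfig, atlas: TractAtlas,
                             n_controls: int = 10) -> list[np.ndarray]:
    """Per-control streamline visitation maps for disconnectome construction.

    Each healthy control contributes a jittered copy of the atlas (integer
    voxel shifts and a random intensity factor), emulating inter-individual
    variability of tract geometry.
    """
    rng = _rng(config, "visitation")
    maps = []
    for _ in range(n_controls):
        combined = np.zeros(config.grid_shape, dtype=float)
        for arr in atlas.tracts.values():
            shift = rng.integers(-1, 2, size=3)
            shifted = np.roll(arr, shift, axis=(0, 1, 2))
            combined = np.maximum(combined, shifted * rng.uniform(0.75, 1.0))
        maps.append(combined)
    return maps


# ---------------------------------------------------------------------------
# tactile matching tables
# ---------------------------------------------------------------------------

VISITS = ("admission", "3mo", "9mo")
SEQUENCES = ("uHuH", "aHaH", "aHuH", "uHaH")


def generate_matching_tables(config: CohortConfig) -> pd.DataFrame:
    """Generate matching-task count tables (long format).

    One row per patient x visit x sequence with the number of correctly
    identified replicas out of 10.  Only subgroups with configured matching
    parameters (PTI and RTI) perform the task.  A per-patient matching
    ability factor couples the twelve cells of each patient.
    """
    rng = _rng(config, "matching")
    rows = []
    for group in config.groups_present():
        if group not in config.matching_params:
            continue
        n = config.n_per_group[group]
        w = rng.standard_normal(n)
        for i, pid in enumerate(_patient_ids(group, n)):
            for visit in VISITS:
                for seq in SEQUENCES:
                    med, lo, hi = config.matching_params[group][visit][seq]
                    t = 0.55 * w[i] + np.sqrt(1 - 0.55 ** 2) * rng.standard_normal()
                    q = stats.norm.cdf(t)
                    count = float(split_truncnorm_ppf(np.array([q]), med, lo, hi)[0])
                    count = int(np.clip(round(count), lo, hi))
                    rows.append({"patient_id": pid, "subgroup": group,
                                 "visit": visit, "sequence": seq,
                                 "correct": count})
    return pd.DataFrame(rows)
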