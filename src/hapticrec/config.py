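"""Configuration objects for the synthetic cohort and the full pipeline.

The default :class:`CohortConfig` encodes the study conditions the analysis
assumes: three patient subgroups (persistent impairment PTI, recovered RTI,
and TOR-normal TN) whose behavioral scores follow the published group
medians and ranges, a healthy control reference for z-scoring, a toy
white-matter tract atlas on a 48x48x48 grid of 2 mm isotropic voxels, and
subgroup-specific lesion/tract overlap targets.

Score distributions are split truncated normals: the subgroup median is the
location, the range gives the truncation bounds, and each half-range spans
``marginal_spread`` SDs of its half-normal (default 3, concentrating mass
near the median while keeping the published range as support).  Patients
within a subgroup share two latent factors — a sensori-motor severity
factor (dominating the timed picking-small-objects test, pressure
thresholds and clinical severity) and a tactile-discrimination factor
(dominating shape discrimination and object recognition, and driving the
nine-month outcome) — which plant the correlation structure the PCA
cascade is designed to uncover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = ["CohortConfig", "SUBGROUPS", "MEASURES", "DEFAULT_SCORE_PARAMS"]

SUBGROUPS = ("PTI", "RTI", "TN")

#: Behavioral measures at admission submitted to the PCA, in canonical order.
MEASURES = ("age", "lesvol", "nih", "ppt0", "mic0", "mac0", "pso0", "tor0")

#: Per-subgroup (median, low, high) targets for every generated measure.
#: MIC/MAC are proportions correct (out of 24 pairs); TOR counts out of 30.
DEFAULT_SCORE_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "TN": {
        "age": (66.5, 41.0, 80.0),
        "lesvol": (4.5, 0.5, 61.0),
        "nih": (4.0, 1.0, 7.0),
        "ppt0": (10.0, 7.0, 59.2),
        "mic0": (0.854, 0.417, 1.0),
        "mac0": (0.958, 0.792, 1.0),
        "pso0": (10.6, 5.3, 26.9),
        "tor0": (30.0, 24.0, 30.0),
        "tor3": (30.0, 28.0, 30.0),
        "tor9": (30.0, 27.0, 30.0),
    },
    "RTI": {
        "age": (75.0, 51.0, 82.0),
        "lesvol": (18.5, 3.4, 44.1),
        "nih": (4.0, 3.0, 6.0),
        "ppt0": (59.2, 9.0, 178.0),
        "mic0": (0.417, 0.0, 0.917),
        "mac0": (0.583, 0.0, 0.833),
        "pso0": (22.0, 10.9, 76.1),
        "tor0": (4.0, 0.0, 20.0),
        "tor3": (25.0, 18.0, 28.0),
        "tor9": (25.0, 19.0, 30.0),
    },
    "PTI": {
        "age": (54.0, 49.0, 70.0),
        "lesvol": (44.1, 22.0, 272.3),
        "nih": (6.0, 3.0, 14.0),
        "ppt0": (158.2, 37.3, 1770.0),
        "mic0": (0.0, 0.0, 0.542),
        "mac0": (0.0, 0.0, 0.625),
        "pso0": (33.1, 12.3, 67.1),
        "tor0": (0.0, 0.0, 3.0),
        "tor3": (4.0, 0.0, 6.0),
        "tor9": (3.0, 0.0, 10.0),
    },
}

#: Healthy-control distributions per measure: (mean, sd, low, high) on the
#: measurement scale, except PPT which is parameterized on log10 g/mm^2
#: (monofilaments are graded logarithmically).
DEFAULT_CONTROL_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "ppt0": (1.0, 0.45, 0.6, 1.8),       # log10 scale
    "mic0": (0.90, 0.22, 0.75, 1.0),
    "mac0": (0.96, 0.04, 0.84, 1.0),
    "pso0": (10.6, 2.0, 5.0, 20.0),
    "tor0": (29.0, 0.72, 26.0, 30.0),
}

#: Latent loadings (severity s, tactile-discrimination v) per measure.  The
#: residual variance is 1 - s^2 - v^2.
DEFAULT_FACTOR_LOADINGS: dict[str, tuple[float, float]] = {
    "age": (0.0, 0.0),
    "lesvol": (0.60, 0.10),
    "nih": (0.92, 0.10),
    "ppt0": (0.92, 0.10),
    "mic0": (0.23, 0.31),
    "mac0": (0.10, 0.90),
    "pso0": (0.90, -0.25),
    "tor0": (0.15, 0.75),
    "tor3": (0.15, 0.75),
    "tor9": (0.15, 0.80),
}

#: Subgroup (mean, sd) of the fractional lesion overlap with the toy
#: anterior arcuate fasciculus.
DEFAULT_TRACT_OVERLAP: dict[str, tuple[float, float]] = {
    "PTI": (0.68, 0.21),
    "RTI": (0.27, 0.24),
    "TN": (0.10, 0.15),
}

#: Per-subgroup (median, low, high) of correct matches (out of 10) for each
#: matching sequence at each visit.  Sequences: uHuH, aHaH, aHuH, uHaH.
DEFAULT_MATCHING_PARAMS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "PTI": {
        "admission": {"uHuH": (8, 5, 10), "aHaH": (0, 0, 0),
                      "aHuH": (3, 0, 4), "uHaH": (5, 1, 8)},
        "3mo": {"uHuH": (10, 5, 10), "aHaH": (0, 0, 5),
                "aHuH": (4, 0, 6), "uHaH": (5, 5, 10)},
        "9mo": {"uHuH": (10, 9, 10), "aHaH": (6, 0, 8),
                "aHuH": (5, 0, 9), "uHaH": (9, 7, 10)},
    },
    "RTI": {
        "admission": {"uHuH": (9, 4, 10), "aHaH": (1, 0, 8),
                      "aHuH": (3, 0, 8), "uHaH": (8, 5, 10)},
        "3mo": {"uHuH": (9, 5, 10), "aHaH": (6, 0, 10),
                "aHuH": (6, 0, 9), "uHaH": (9, 5, 10)},
        "9mo": {"uHuH": (10, 5, 10), "aHaH": (8, 7, 10),
                "aHuH": (9, 4, 10), "uHaH": (10, 9, 10)},
    },
}

#: Fraction of male patients per subgroup (from the published sex split).
DEFAULT_MALE_FRACTION = {"TN": 18 / 22, "RTI": 5 / 7, "PTI": 6 / 7}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``n_per_group`` maps subgroup labels to patient counts (default 7 PTI,
    7 RTI, 22 TN).  A count of zero omits the subgroup; single-patient
    groups are rejected because no spread target can be met.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PTI": 7, "RTI": 7, "TN": 22})
    n_controls: int = 20
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    score_params: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_SCORE_PARAMS.items()})
    control_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_PARAMS))
    factor_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADINGS))
    tract_overlap_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRACT_OVERLAP))
    matching_params: dict = field(
        default_factory=lambda: {g: {v: dict(s) for v, s in vs.items()}
                                 for g, vs in DEFAULT_MATCHING_PARAMS.items()})
    n_plegic: dict[str, int] = field(
        default_factory=lambda: {"PTI": 2, "RTI": 1, "TN": 0})
    #: half-range of each score marginal in SDs of its half-normal; larger
    #: values concentrate mass near the subgroup median while keeping the
    #: published range as the support
    marginal_spread: float = 3.0
    #: per-measure overrides of ``marginal_spread`` (e.g. the roughness
    #: discrimination task spans its whole range in the impaired subgroups)
    marginal_spread_overrides: dict[str, float] = field(
        default_factory=lambda: {"mic0": 1.5, "tor0": 1.8})
    male_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for grp, n in self.n_per_group.items():
            if grp not in SUBGROUPS:
                raise ValueError(f"unknown subgroup {grp!r}")
            if n < 0 or n == 1:
                raise ValueError(
                    f"subgroup {grp}: count must be 0 or >= 2, got {n}")
        if sum(self.n_per_group.values()) == 0:
            raise ValueError("cohort is empty")
        if self.n_controls < 2:
            raise ValueError("need at least two healthy controls")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3-D with every side >= 8")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        for grp, measures in self.score_params.items():
            for m, (med, lo, hi) in measures.items():
                if not lo <= med <= hi:
                    raise ValueError(
                        f"{grp}/{m}: median {med} outside range [{lo}, {hi}]")
        for m, (mean, sd, lo, hi) in self.control_params.items():
            if sd <= 0:
                raise ValueError(f"control {m}: SD must be > 0")
            if not lo <= mean <= hi:
                raise ValueError(f"control {m}: mean outside bounds")
        for m, (a, b) in self.factor_loadings.items():
            if a * a + b * b > 1.0 + 1e-12:
                raise ValueError(f"{m}: factor loadings exceed unit variance")
        for grp, (mean, sd) in self.tract_overlap_params.items():
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"{grp}: overlap mean must lie in [0, 1]")
            if sd < 0:
                raise ValueError(f"{grp}: overlap SD must be >= 0")
        for grp, k in self.n_plegic.items():
            if k < 0:
                raise ValueError(f"{grp}: invalid plegic count {k}")

    def groups_present(self) -> list[str]:
        return [g for g in SUBGROUPS if self.n_per_group.get(g, 0) > 0]

    def to_dict(self) -> dict:
        return asdict(self)


def config_from_mapping(data: Mapping) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML/JSON mapping.

    Unknown keys are rejected so that typos in configuration files fail
    before any computation.
    """
    allowed = set(CohortConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "n_per_group" in kwargs:
        kwargs["n_per_group"] = {str(k): int(v)
                                 for k, v in kwargs["n_per_group"].items()}
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(int(v) for v in kwargs["grid_shape"])
    return CohortConfig(**kwargs)
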