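"""Raw behavioral scores -> impairment-signed z-score feature matrix.

Behavioral measures are z-scored against gender- and hand-matched healthy
controls (the affected hand of each patient is matched to the corresponding
control hand).  Measures where a larger raw value means worse performance
(picking-small-objects time, pressure threshold) are sign-flipped so that
more negative z always means more impaired.  Age and lesion volume are
z-scored within the patient cohort (by default the 14 impaired patients,
the PCA sample); the NIH stroke scale enters untransformed, its magnitude
being already comparable to a z-score.  The pressure perception threshold
is compared on the log10 scale, matching the logarithmic grading of
monofilaments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MEASURES
from .synthetic_cohort import ControlReference

__all__ = ["ZMatrix", "to_zscores", "impute_plegic_pso", "assemble_features"]

logger = logging.getLogger(__name__)

#: raw orientation: larger value = worse performance -> sign flip after z
FLIPPED = ("pso0", "ppt0")
#: measures passed through without control normalization
PASSTHROUGH = ("nih",)
#: measures normalized within the patient cohort rather than vs controls
COHORT_NORMALIZED = ("age", "lesvol")


@dataclass
class ZMatrix:
    """Patients x measures matrix of impairment-signed z-scores.

    ``oriented`` flags measures that obey the convention "more negative =
    more impaired" (all except the raw NIH score, which runs the other
    way and is deliberately left untouched).  ``center`` records the
    reference mean subtracted per measure and ``scale`` the SD divided by,
    for provenance; cohort-normalized and pass-through measures record the
    normalization actually applied.
    """

    data: pd.DataFrame               # index: patient_id, columns: measures
    oriented: dict[str, bool]
    center: dict[str, float | None] = field(default_factory=dict)
    scale: dict[str, float | None] = field(default_factory=dict)

    @property
    def measures(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def save(self, csv_path: str | Path) -> None:
        """CSV with a JSON sidecar recording normalization provenance."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path)
        sidecar = {
            "oriented": self.oriented,
            "center": self.center,
            "scale": self.scale,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "ZMatrix":
        csv_path = Path(csv_path)
        data = pd.read_csv(csv_path, index_col=0)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(data=data, oriented=meta["oriented"],
                   center=meta["center"], scale=meta["scale"])


def impute_plegic_pso(table: pd.DataFrame,
                      strategy: str = "max_observed") -> pd.DataFrame:
    """Fill the missing admission PSO of plegic patients.

    Patients with plegic fingers cannot perform the timed picking-small-
    objects test at admission.  The default ``max_observed`` strategy
    assigns the slowest time observed in the patient's subgroup — a
    conservative stand-in, since any completed time would have been at
    least that slow.  The ``trajectory_intercept`` strategy would use
    recovery-trajectory intercepts from longitudinal follow-up data; without
    such data it falls back to ``max_observed`` with a warning.
    """
    if strategy not in ("max_observed", "trajectory_intercept"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if strategy == "trajectory_intercept":
        logger.warning("trajectory_intercept requires longitudinal trajectory "
                       "data; falling back to max_observed")
        strategy = "max_observed"
    out = table.copy()
    missing = out["pso0"].isna()
    if not missing.any():
        return out
    for group, sub in out.groupby("subgroup"):
        miss = sub["pso0"].isna()
        if not miss.any():
            continue
        observed = sub.loc[~miss, "pso0"]
        if observed.empty:
            raise ValueError(
                f"subgroup {group}: all patients plegic, no observed PSO to "
                "anchor the imputation")
        out.loc[sub.index[miss], "pso0"] = float(observed.max())
    return out


def to_zscores(raw: pd.DataFrame, ref: ControlReference,
               cohort_norm_subgroups: tuple[str, ...] = ("PTI", "RTI"),
               ) -> ZMatrix:
    """Convert the raw score table to the impairment-signed z-score matrix.

    ``cohort_norm_subgroups`` selects the normalizing sample for age and
    lesion volume (default: the impaired patients, i.e. the PCA cohort);
    z-scores are nevertheless produced for every row of ``raw``.

    Raises ``KeyError`` naming the missing (measure, gender, hand) cell if
    the control reference is incomplete, and ``ValueError`` if PSO is still
    missing (impute first).
    """
    if raw["pso0"].isna().any():
        bad = raw.loc[raw["pso0"].isna(), "patient_id"].tolist()
        raise ValueError(f"missing PSO at admission for {bad}; run "
                         "impute_plegic_pso first")
    z = pd.DataFrame(index=raw["patient_id"])
    oriented: dict[str, bool] = {}
    center: dict[str, float | None] = {}
    scale: dict[str, float | None] = {}

    norm_sample = raw[raw["subgroup"].isin(cohort_norm_subgroups)]
    if len(norm_sample) < 2:
        norm_sample = raw
    for measure in COHORT_NORMALIZED:
        mu = float(norm_sample[measure].mean())
        sd = float(norm_sample[measure].std(ddof=1))
        if sd == 0:
            sd = 1.0
        z[measure] = ((raw[measure] - mu) / sd).to_numpy()
        oriented[measure] = False  # direction carries no impairment meaning
        center[measure], scale[measure] = mu, sd

    for measure in PASSTHROUGH:
        z[measure] = raw[measure].to_numpy()
        oriented[measure] = False  # raw NIH: larger = worse, kept as published
        center[measure], scale[measure] = None, None

    for measure in ("ppt0", "mic0", "mac0", "pso0", "tor0"):
        vals = np.empty(len(raw))
        for i, (_, row) in enumerate(raw.iterrows()):
            mu, sd, scl = ref.lookup(measure, row["gender"], row["affected_side"])
            x = row[measure]
            if scl == "log10":
                x = np.log10(x)
            zz = (x - mu) / sd
            if measure in FLIPPED:
                zz = -zz
            vals[i] = zz
        z[measure] = vals
        oriented[measure] = True
        center[measure], scale[measure] = None, None  # per-cell, see sidecar
    order = [m for m in MEASURES if m in z.columns]
    z = z[order]
    return ZMatrix(data=z, oriented=oriented, center=center, scale=scale)


def assemble_features(z: ZMatrix, measures: list[str]) -> ZMatrix:
    """Restrict the z-matrix to the requested measures, in the given order."""
    if not measures:
        raise ValueError("empty measure list")
    unknown = [m for m in measures if m not in z.data.columns]
    if unknown:
        raise KeyError(f"unknown measures {unknown}; have {z.measures}")
    return ZMatrix(data=z.data[list(measures)].copy(),
                   oriented={m: z.oriented[m] for m in measures},
                   center={m: z.center.get(m) for m in measures},
                   scale={m: z.scale.get(m) for m in measures})
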