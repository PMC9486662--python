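"""Tactile matching-task analysis: interhemispheric haptic transfer.

Four exploration sequences probe haptic information flow: uH:uH and aH:aH
(presentation and matching with the same hand, unaffected or affected)
need a single hemisphere, while aH:uH and uH:aH (alternated hands) require
interhemispheric transfer via the corpus callosum.  The affected-hand
aH:aH sequence serves as the within-patient reference: improvement in
uH:aH but not aH:uH relative to it marks unidirectional transfer from the
unaffected toward the affected hand.

Per group x visit the report gives medians and ranges per sequence,
Mann-Whitney comparisons of each other sequence against the aH:aH
reference (Bonferroni over the three comparisons) and Friedman tests over
the four sequences per visit and over the three visits per sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .smallsample_stats import bonferroni, friedman, mann_whitney_z
from .synthetic_cohort import SEQUENCES, VISITS

__all__ = ["transfer_report", "transfer_asymmetry"]

_REFERENCE = "aHaH"
_COMPARISONS = [("uHuH", _REFERENCE), ("aHuH", _REFERENCE), ("uHaH", _REFERENCE)]


def _wide(tables: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = tables[tables.subgroup == group]
    wide = sub.pivot_table(index="patient_id", columns=["visit", "sequence"],
                           values="correct")
    expected = [(v, s) for v in VISITS for s in SEQUENCES]
    missing = [c for c in expected if c not in wide.columns]
    if missing:
        raise ValueError(f"group {group}: missing cells {missing}")
    return wide


def transfer_report(tables: pd.DataFrame) -> pd.DataFrame:
    """Group x visit matching-task report (one row per group x visit).

    ``tables`` is the long-format count table (patient_id, subgroup, visit,
    sequence, correct).  Patients with incomplete cells are excluded from
    the affected comparisons with a warning row count.  P-values of the
    three sequence-vs-reference Mann-Whitney tests are Bonferroni-corrected
    within each group x visit family (m = 3).
    """
    rows = []
    for group in sorted(tables.subgroup.unique()):
        sub = tables[tables.subgroup == group]
        complete = sub.groupby("patient_id")["correct"].count() == len(VISITS) * len(SEQUENCES)
        keep = complete[complete].index
        if len(keep) < 2:
            raise ValueError(f"group {group}: fewer than two complete patients")
        wide = _wide(sub[sub.patient_id.isin(keep)], group)
        for visit in VISITS:
            row: dict = {"subgroup": group, "visit": visit,
                         "n": len(wide),
                         "n_excluded": int((~complete).sum())}
            for seq in SEQUENCES:
                vals = wide[(visit, seq)]
                row[f"{seq}_median"] = float(vals.median())
                row[f"{seq}_min"] = float(vals.min())
                row[f"{seq}_max"] = float(vals.max())
            raw_p = []
            for seq, ref in _COMPARISONS:
                res = mann_whitney_z(wide[(visit, seq)], wide[(visit, ref)])
                row[f"z_{seq}_vs_{ref}"] = res.value
                raw_p.append(res.p)
            for (seq, ref), p in zip(_COMPARISONS, bonferroni(raw_p)):
                row[f"p_{seq}_vs_{ref}"] = p
            fr = friedman(wide[visit][list(SEQUENCES)].to_numpy())
            row["friedman_sequences_chi2"] = fr.value
            row["friedman_sequences_p"] = fr.p
            rows.append(row)
        # Friedman over the three visits, per sequence
        for seq in SEQUENCES:
            mat = np.column_stack([wide[(v, seq)] for v in VISITS])
            fr = friedman(mat)
            rows.append({"subgroup": group, "visit": "over_9mo",
                         "n": len(wide), "sequence": seq,
                         "friedman_visits_chi2": fr.value,
                         "friedman_visits_p": fr.p})
    return pd.DataFrame(rows)


def transfer_asymmetry(tables: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Directionality of interhemispheric transfer per group.

    For each group x visit, difference scores (uH:aH - aH:aH) and
    (aH:uH - aH:aH) are tested with two-sided sign tests.  The group's
    direction flag summarizes the last visit: a transfer direction counts
    as *restored* when its median reaches the unaffected-hand (uH:uH)
    reference level within ``restored_margin`` objects; both directions
    restored gives ``bidirectional``, only the unaffected-to-affected
    direction gives ``unidirectional``, neither gives ``none``.
    """
    restored_margin = 2.0
    rows = []
    for group in sorted(tables.subgroup.unique()):
        wide = _wide(tables, group)
        for visit in VISITS:
            row: dict = {"subgroup": group, "visit": visit}
            for seq, name in (("uHaH", "toward_affected"),
                              ("aHuH", "toward_unaffected")):
                diff = wide[(visit, seq)] - wide[(visit, _REFERENCE)]
                nonzero = diff[diff != 0]
                if len(nonzero) == 0:
                    p = 1.0
                else:
                    p = binomtest(int((nonzero > 0).sum()),
                                  len(nonzero)).pvalue
                row[f"{name}_median_diff"] = float(diff.median())
                row[f"{name}_sign_p"] = float(p)
            rows.append(row)
        last = VISITS[-1]
        norm_level = float(wide[(last, "uHuH")].median()) - restored_margin
        toward_aff = float(wide[(last, "uHaH")].median()) >= norm_level
        toward_unaff = float(wide[(last, "aHuH")].median()) >= norm_level
        if toward_aff and toward_unaff:
            flag = "bidirectional"
        elif toward_aff:
            flag = "unidirectional"
        else:
            flag = "none"
        for row in rows:
            if row["subgroup"] == group and "direction_flag" not in row:
                row["direction_flag"] = flag
    return pd.DataFrame(rows)
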