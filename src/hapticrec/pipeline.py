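"""End-to-end pipeline: generate -> prep -> cascade -> validate -> lesions
-> matching -> summary.

The orchestrator only moves data between module operations and serializes
their outputs; every number in the summary is produced by a module call.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavioral_prep import assemble_features, impute_plegic_pso, to_zscores
from .config import CohortConfig
from .lesion_tracts import conjunction_map, disconnection_metrics, \
    group_tract_table
from .matching_transfer import transfer_asymmetry, transfer_report
from .pca_cascade import run_cascade
from .permutation_validation import build_permutation_set, plot_validation, \
    roc_analysis
from .synthetic_cohort import generate_behavioral_cohort, \
    generate_control_reference, generate_lesion_cohort, \
    generate_matching_tables, toy_tract_atlas

logger = logging.getLogger(__name__)

TERMINAL_MEASURES_3D = ("mac0", "pso0", "tor0")


@dataclass
class RunResult:
    summary: dict
    out_dir: Path | None = None
    artifacts: dict = field(default_factory=dict)


def run_all(config: CohortConfig, out_dir: str | Path | None = None,
            make_figures: bool = False, with_lesions: bool = True,
            with_matching: bool = True) -> RunResult:
    """Run the complete analysis on a synthetic cohort.

    Writes (when ``out_dir`` is given) the cohort CSVs, the cascade JSON and
    a Table-3-like stage summary, permutation/ROC CSVs, the tract report and
    the matching report, plus one ``summary.json``; returns everything
    in-memory as well.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "version": __version__}
    artifacts: dict = {}

    stage = "generate"
    try:
        cohort = generate_behavioral_cohort(config)
        ref = generate_control_reference(config)
        artifacts["cohort"] = cohort
        artifacts["control_reference"] = ref
        if out is not None:
            cohort.to_csv(out / "cohort.csv", index=False)
            ref.save(out / "control_reference.csv")

        stage = "prep"
        imputed = impute_plegic_pso(cohort)
        z = to_zscores(imputed, ref)
        artifacts["zmatrix"] = z
        if out is not None:
            z.save(out / "zscores.csv")

        stage = "cascade"
        impaired = imputed[imputed.subgroup.isin(["PTI", "RTI"])]
        z_imp = assemble_features(z, z.measures)
        z_imp.data = z_imp.data.loc[impaired.patient_id]
        tor9 = impaired["tor9"].to_numpy(float)
        labels = impaired["subgroup"].to_numpy()
        cascade = run_cascade(z_imp, tor9, labels)
        artifacts["cascade"] = cascade
        if out is not None:
            cascade.to_json(out / "cascade.json")
            cascade.summary_table().to_csv(out / "cascade_stages.csv",
                                           index=False)
        terminal = cascade.terminal_stage
        summary["terminal_measures"] = cascade.terminal_measures
        summary["cascade_inconclusive"] = cascade.inconclusive
        summary["salient_component"] = terminal.salient.component + 1
        summary["salient_r_tor9"] = terminal.salient.r
        summary["salient_p_tor9"] = terminal.salient.p
        summary["kw_chi2"] = terminal.salient.kw_chi2
        summary["kw_p"] = terminal.salient.kw_p
        summary["discrimination_threshold"] = cascade.terminal_threshold

        stage = "validate"
        if not cascade.inconclusive and len(cascade.terminal_measures) == 3:
            tn = imputed[imputed.subgroup == "TN"]
            zt = assemble_features(z, cascade.terminal_measures)
            tn_ref = zt.data.loc[tn.patient_id].to_numpy(float)
            perm_sets = {}
            for grp in ("RTI", "PTI"):
                ids = impaired.loc[impaired.subgroup == grp, "patient_id"]
                vals = zt.data.loc[ids].to_numpy(float)
                perm_sets[grp] = build_permutation_set(
                    vals, grp, tn_ref, terminal.pca,
                    terminal.salient.component)
            scores = np.concatenate([perm_sets[g].accepted_scores
                                     for g in ("RTI", "PTI")])
            perm_labels = np.concatenate(
                [[g] * perm_sets[g].n_accepted for g in ("RTI", "PTI")])
            roc = roc_analysis(scores, perm_labels, positive_class="RTI")
            artifacts["permutation_sets"] = perm_sets
            artifacts["roc"] = roc
            summary["n_recombinations"] = {
                g: int(len(perm_sets[g].triples)) for g in perm_sets}
            summary["n_accepted"] = {g: perm_sets[g].n_accepted
                                     for g in perm_sets}
            summary["mahalanobis_limits"] = {
                g: list(perm_sets[g].limits) for g in perm_sets}
            summary["roc"] = {"auc": roc.auc,
                              "optimal_threshold": roc.optimal_threshold,
                              "tpr": roc.tpr_at_optimum,
                              "fpr": roc.fpr_at_optimum,
                              "youden_j": roc.youden_j,
                              "balanced_accuracy": roc.balanced_accuracy}
            if out is not None:
                roc.curve_frame().to_csv(out / "roc_curve.csv", index=False)
                pd.DataFrame({
                    "subgroup": perm_labels, "score": scores,
                }).to_csv(out / "simulated_scores.csv", index=False)
                if make_figures:
                    plot_validation(perm_sets, roc, out / "validation.png")

        if with_lesions:
            stage = "lesions"
            atlas = toy_tract_atlas(config)
            masks = generate_lesion_cohort(config, atlas)
            artifacts["atlas"] = atlas
            artifacts["masks"] = masks
            label_map = dict(zip(cohort.patient_id, cohort.subgroup))
            summaries = [
                disconnection_metrics(m, atlas.tracts[t], tract_name=t)
                for m in masks for t in atlas.tracts
            ]
            tract_table = group_tract_table(summaries, label_map)
            artifacts["tract_table"] = tract_table
            summary["tract_tests"] = {
                row["tract"]: {"t_PTI_vs_RTI": row["t_PTI_vs_RTI"],
                               "anova_F": row["anova_F"]}
                for _, row in tract_table.iterrows()
            }
            tn_masks = [m for m in masks if label_map[m.patient_id] == "TN"]
            if tn_masks:
                conj = conjunction_map(tn_masks, fraction=0.714)
                summary["conjunction_threshold_patients"] = \
                    conj.threshold_patients
            if out is not None:
                tract_table.to_csv(out / "tract_report.csv", index=False)

        if with_matching:
            stage = "matching"
            matching = generate_matching_tables(config)
            if not matching.empty:
                report = transfer_report(matching)
                asym = transfer_asymmetry(matching)
                artifacts["matching"] = matching
                artifacts["matching_report"] = report
                artifacts["matching_asymmetry"] = asym
                summary["transfer_flags"] = {
                    g: asym.loc[asym.subgroup == g, "direction_flag"].iloc[0]
                    for g in asym.subgroup.unique()
                }
                if out is not None:
                    matching.to_csv(out / "matching.csv", index=False)
                    report.to_csv(out / "matching_report.csv", index=False)
                    asym.to_csv(out / "matching_asymmetry.csv", index=False)
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        if out is not None:
            (out / "FAILED_STAGE.txt").write_text(stage)
        raise

    summary["elapsed_s"] = round(time.time() - t0, 3)
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return RunResult(summary=summary, out_dir=out, artifacts=artifacts)
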