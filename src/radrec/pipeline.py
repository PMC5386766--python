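"""Stage orchestration: simulate → perfusion → features → classify →
survive → histo → report.

Stages communicate only through files (NIfTI / CSV / JSON), so any stage
can be re-run from cached upstream outputs and reproduce downstream
results exactly.  Every report embeds a provenance block (config hash,
seed, package version) and contains no timestamps, so identical
configuration yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    GREATER,
    LESSER,
    ConjunctionRuleClassifier,
    ThresholdRule,
    best_cutoff,
    confusion_metrics,
    delong_compare,
    fisher_exact,
    group_compare,
    loocv_accuracy,
    roc_analysis,
    stepwise_logistic,
)
from .features import assemble_features
from .histology import (
    compare_foci_groups,
    group_average_proportion,
    read_foci_table,
)
from .io import (
    read_cohort,
    read_mask,
    read_series,
    read_volume,
    write_cohort,
    write_mask,
    write_series,
    write_volume,
)
from .perfusion import compute_ncbv_map
from .survival import km_fit, logrank_test
from .swi import pro_swmri, reference_signal
from .synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_dsc_phantom,
    generate_swmri_phantom,
)
from .types import CohortTable, ValidationError

SINGLE_VARIABLES = (
    ("mean_ncbv", GREATER),
    ("ncbv90", GREATER),
    ("pro_swmri", LESSER),
)


def _provenance(config: dict, seed: int) -> dict:
    digest = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()
    return {"config_sha256": digest, "seed": int(seed), "version": __version__}


# ---------------------------------------------------------------------------
# stage: simulate


def stage_simulate(config: SyntheticConfig, out_dir) -> dict:
    """Write phantom NIfTIs, masks, a truth JSON and a feature-level cohort
    CSV; return the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, masks, truth = generate_dsc_phantom(config)
    write_series(series, out / "dsc_series.nii.gz")
    swi, swi_masks, dark = generate_swmri_phantom(config)
    write_volume(swi, out / "swmri.nii.gz")
    for name, mask in masks.items():
        write_mask(mask, out / f"mask_{name}.nii.gz")
    cohort, cohort_truth = generate_cohort(config)
    write_cohort(cohort, out / "cohort.csv")
    truth_json = {
        "seed": config.seed,
        "lesion_cbv_ratio": config.lesion_cbv_ratio,
        "lesion_k2": config.lesion_k2,
        "dark_fraction": dark,
        "cohort": cohort_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True, default=str)
    return {
        "series": str(out / "dsc_series.nii.gz"),
        "swmri": str(out / "swmri.nii.gz"),
        "cohort": str(out / "cohort.csv"),
        "truth": str(out / "truth.json"),
    }


# ---------------------------------------------------------------------------
# stage: perfusion


def stage_perfusion(
    series_path,
    reference_mask_path,
    nawm_mask_path,
    lesion_mask_path,
    out_dir,
    tr_seconds: float = 1.5,
    te_seconds: float = 0.035,
    n_baseline: int = 4,
    order: str = "correct_then_fit",
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = read_series(series_path, tr_seconds, te_seconds, n_baseline)
    ref_mask = read_mask(reference_mask_path, role="nonenhancing_reference", grid_shape=series.grid_shape)
    nawm = read_mask(nawm_mask_path, role="nawm", grid_shape=series.grid_shape)
    lesion = read_mask(lesion_mask_path, role="lesion", grid_shape=series.grid_shape)
    process = lesion.voxels | nawm.voxels
    ncbv, qc = compute_ncbv_map(series, ref_mask, nawm, voxel_mask=process, order=order)
    write_volume(ncbv, out / "ncbv.nii.gz")
    qc.to_csv(out / "perfusion_qc.csv", index=False)
    return {"ncbv": str(out / "ncbv.nii.gz"), "qc": str(out / "perfusion_qc.csv")}


# ---------------------------------------------------------------------------
# stage: features


def stage_features(
    ncbv_path, swmri_path, lesion_mask_path, ventricle_mask_path, out_path,
    patient_id: str = "subject-001",
) -> dict:
    ncbv = read_volume(ncbv_path, role="ncbv")
    swi = read_volume(swmri_path, role="swmri")
    lesion = read_mask(lesion_mask_path, role="lesion", grid_shape=ncbv.grid_shape)
    ventricle = read_mask(ventricle_mask_path, role="ventricle", grid_shape=swi.grid_shape)
    ref = reference_signal(swi, ventricle)
    pro = pro_swmri(swi, lesion, ref)
    feats = assemble_features(ncbv, lesion, pro)
    row = {"patient_id": patient_id, **feats.as_dict()}
    pd.DataFrame([row]).to_csv(out_path, index=False)
    return row


# ---------------------------------------------------------------------------
# stage: classify


def classify_cohort(cohort: CohortTable, fixed_rule: ThresholdRule | None = None) -> dict:
    """Full diagnostic-performance report on a featured cohort.

    Per single variable: AUC with DeLong 95% CI, Youden cutoff, confusion
    metrics.  Combined: stepwise-logistic linear predictor AUC (the
    combined ROC) and the conjunction rule's confusion metrics, DeLong
    comparison against nCBV90 alone, Fisher comparison of the two
    specificities, and LOOCV accuracy of the conjunction rule.
    """
    frame = cohort.to_frame()
    y = cohort.labels()
    report: dict = {"n": len(cohort), "variables": {}}
    for var, direction in SINGLE_VARIABLES:
        roc = roc_analysis(frame[var].to_numpy(), y, direction=direction)
        cut = best_cutoff(roc)
        if direction == GREATER:
            preds = np.where(frame[var] > cut.cutoff, "recurrence", "radionecrosis")
        else:
            preds = np.where(frame[var] <= cut.cutoff, "recurrence", "radionecrosis")
        cm = confusion_metrics(preds, y)
        t_stat, t_p = group_compare(
            frame.loc[y == "recurrence", var],
            frame.loc[y == "radionecrosis", var],
            method="t_test",
        )
        report["variables"][var] = {
            "auc": roc.auc,
            "auc_ci95": list(roc.auc_ci95),
            "cutoff": cut.cutoff,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "accuracy": cm.accuracy,
            "counts": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp},
            "t_test_p": t_p,
        }

    frame["grade_iv"] = (frame["grade"] == "IV").astype(float)
    candidates = ["grade_iv", "mean_ncbv", "ncbv90", "pro_swmri"]
    sw = stepwise_logistic(frame, y, candidates)
    combined_roc = roc_analysis(sw.scores, y, direction=GREATER)

    clf = ConjunctionRuleClassifier(
        ncbv90_cutoff=None if fixed_rule is None else fixed_rule.ncbv90_cutoff,
        pro_swmri_cutoff=None if fixed_rule is None else fixed_rule.pro_swmri_cutoff,
    ).fit(frame[["ncbv90", "pro_swmri"]].to_numpy(), y)
    rule = clf.rule_
    conj_preds = clf.predict(frame[["ncbv90", "pro_swmri"]].to_numpy())
    conj_cm = confusion_metrics(conj_preds, y)
    single_cm = report["variables"]["ncbv90"]["counts"]

    dl = delong_compare(
        frame["ncbv90"].to_numpy(), sw.scores, y,
        direction_a=GREATER, direction_b=GREATER,
    )
    n_neg = conj_cm.tn + conj_cm.fp
    fisher_p = fisher_exact(conj_cm.tn, n_neg, single_cm["tn"], n_neg)

    report["stepwise"] = {
        "selected": sw.selected,
        "coefficients": sw.coefficients,
        "separation": bool(sw.separation),
    }
    report["combined"] = {
        "auc": combined_roc.auc,
        "auc_ci95": list(combined_roc.auc_ci95),
        "rule": {"ncbv90_cutoff": rule.ncbv90_cutoff, "pro_swmri_cutoff": rule.pro_swmri_cutoff},
        "sensitivity": conj_cm.sensitivity,
        "specificity": conj_cm.specificity,
        "accuracy": conj_cm.accuracy,
        "counts": {"tp": conj_cm.tp, "fn": conj_cm.fn, "tn": conj_cm.tn, "fp": conj_cm.fp},
        "delong_vs_ncbv90_p": dl.p_value,
        "fisher_specificity_p": fisher_p,
        "loocv_accuracy": loocv_accuracy(cohort),
    }
    return report


def stage_classify(cohort_path, out_dir, fixed_rule: ThresholdRule | None = None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    report = classify_cohort(cohort, fixed_rule=fixed_rule)
    with open(out / "classification.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for var, res in report["variables"].items():
        rows.append(
            {
                "parameter": var,
                "auc": round(res["auc"], 3),
                "cutoff": round(res["cutoff"], 2),
                "sensitivity_pct": round(res["sensitivity"], 1),
                "specificity_pct": round(res["specificity"], 1),
                "accuracy_pct": round(res["accuracy"], 1),
            }
        )
    comb = report["combined"]
    rows.append(
        {
            "parameter": "ncbv90+pro_swmri",
            "auc": round(comb["auc"], 3),
            "cutoff": np.nan,
            "sensitivity_pct": round(comb["sensitivity"], 1),
            "specificity_pct": round(comb["specificity"], 1),
            "accuracy_pct": round(comb["accuracy"], 1),
        }
    )
    pd.DataFrame(rows).to_csv(out / "performance_table.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# stage: survive


def survival_report(cohort: CohortTable, rule: ThresholdRule) -> dict:
    """KM curves per rule stratum, medians with CI, 6/12/24-month rates and
    the log-rank comparison."""
    frame = cohort.to_frame()
    strata = rule.decide(frame["ncbv90"].to_numpy(), frame["pro_swmri"].to_numpy())
    pos = strata == "recurrence"
    if pos.all() or (~pos).all():
        raise ValidationError("rule stratifies the cohort into a single group")
    out = {}
    for name, mask in (("rule_positive", pos), ("rule_negative", ~pos)):
        curve = km_fit(
            frame.loc[mask, "survival_days"], frame.loc[mask, "event"].astype(bool)
        )
        out[name] = {
            "n": int(mask.sum()),
            "median_days": curve.median_days,
            "median_ci95": list(curve.median_ci95),
            "rates_pct": {str(m): r for m, r in curve.rates_at_months().items()},
        }
    lr = logrank_test(
        frame.loc[pos, "survival_days"],
        frame.loc[pos, "event"].astype(bool),
        frame.loc[~pos, "survival_days"],
        frame.loc[~pos, "event"].astype(bool),
    )
    out["logrank"] = {"chi_square": lr.chi_square, "p_value": lr.p_value}
    return out


def stage_survive(cohort_path, out_dir, rule: ThresholdRule) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    report = survival_report(cohort, rule)
    with open(out / "survival.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    frame = cohort.to_frame()
    strata = rule.decide(frame["ncbv90"].to_numpy(), frame["pro_swmri"].to_numpy())
    rows = []
    for name in ("recurrence", "radionecrosis"):
        mask = strata == name
        curve = km_fit(frame.loc[mask, "survival_days"], frame.loc[mask, "event"].astype(bool))
        for t, s, r in zip(curve.event_times, curve.survival_prob, curve.n_at_risk):
            rows.append(
                {
                    "stratum": "rule_positive" if name == "recurrence" else "rule_negative",
                    "days": t,
                    "survival": s,
                    "n_at_risk": r,
                }
            )
    pd.DataFrame(rows).to_csv(out / "km_curves.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# stage: histo


def stage_histo(foci_path, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_foci_table(foci_path)
    report = {
        "avr": {
            group: {
                size: group_average_proportion(records, group, size)
                for size in ("small", "large")
            }
            for group in ("radionecrosis", "recurrence")
        },
        "mann_whitney_p_small": compare_foci_groups(records, "small"),
        "mann_whitney_p_large": compare_foci_groups(records, "large"),
    }
    with open(out / "histology.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: SyntheticConfig, out_dir, foci_path=None) -> dict:
    """End-to-end seeded run on synthetic inputs; returns the report bundle
    and writes report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = stage_simulate(config, out / "simulate")
    perf = stage_perfusion(
        files["series"],
        out / "simulate" / "mask_nonenhancing_reference.nii.gz",
        out / "simulate" / "mask_nawm.nii.gz",
        out / "simulate" / "mask_lesion.nii.gz",
        out / "perfusion",
        tr_seconds=config.tr_seconds,
        te_seconds=config.te_seconds,
        n_baseline=config.n_baseline,
    )
    feature_row = stage_features(
        perf["ncbv"],
        files["swmri"],
        out / "simulate" / "mask_lesion.nii.gz",
        out / "simulate" / "mask_ventricle.nii.gz",
        out / "features.csv",
    )
    classification = stage_classify(files["cohort"], out / "classify")
    survival = stage_survive(files["cohort"], out / "survive", config.rule)
    histo = stage_histo(foci_path, out / "histo")
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    cfg_dict["rule"] = {"ncbv90_cutoff": config.rule.ncbv90_cutoff, "pro_swmri_cutoff": config.rule.pro_swmri_cutoff}
    bundle = {
        "provenance": _provenance(cfg_dict, config.seed),
        "phantom_features": feature_row,
        "classification": classification,
        "survival": survival,
        "histology": histo,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    return bundle
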