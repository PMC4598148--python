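"""End-to-end study pipeline: simulate -> quantify -> classify -> report.

``run_study`` executes the whole chain on one cohort configuration and writes
every intermediate artifact (images, CSV tables) plus a machine-readable
report.  All group statistics are recomputable from the on-disk CSVs, and a
fixed (config, seed) pair reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortConfig, config_hash
from .fluorescence import quantify_directory
from .mri import quantify_mri_directory
from .roc import (
    LabeledScores,
    optimal_cutoff,
    optimize_combination,
    roc_curve,
    unpaired_t_test,
)
from .synthetic import generate_cohort, write_cohort

__all__ = ["run_study", "summarize_groups", "build_report", "rebuild_report"]

log = logging.getLogger("plaqrisk")

PREDICTORS = ["fer", "rr", "gdr"]


def summarize_groups(values) -> dict:
    """Sample mean and SD (n-1 denominator) of one group.

    A single-value group has an undefined SD; it is reported as 0 with a
    ``degenerate`` flag rather than NaN.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty group")
    degenerate = v.size == 1
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": 0.0 if degenerate else float(v.std(ddof=1)),
        "degenerate": bool(degenerate),
    }


def _roc_entry(scores, labels) -> dict:
    data = LabeledScores(np.asarray(scores, float), np.asarray(labels, bool))
    roc = roc_curve(data)
    cut = optimal_cutoff(roc)
    return {
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "failed": roc.failed,
        "n_positive": roc.n_positive,
        "n_negative": roc.n_negative,
        "cutoff": cut.threshold,
        "sensitivity": cut.sensitivity,
        "specificity": cut.specificity,
        "youden_j": cut.youden_j,
    }


def build_report(
    table: pd.DataFrame,
    open_view: pd.DataFrame,
    step_pct: int = 5,
    predictors: list[str] | None = None,
) -> dict:
    """Per-arm statistics from the merged analysis table.

    ``table`` carries one row per segment with columns (rabbit_id, probe,
    segment_index, disrupted, fer, rr, gdr); ``open_view`` one row per
    disrupted site with (rabbit_id, thrombus_fer, plaque_fer).  For each arm:
    group means +- SD with the unpaired t-test, single-predictor ROC results,
    and the grid-optimized combined predictor.
    """
    predictors = predictors or PREDICTORS
    probes = {
        rid: probe for rid, probe in zip(table["rabbit_id"], table["probe"])
    }
    report: dict = {"arms": {}}
    for probe in sorted(table["probe"].unique()):
        arm_tab = table[table["probe"] == probe]
        arm_open = open_view[
            open_view["rabbit_id"].map(probes).eq(probe)
        ] if len(open_view) else open_view
        disrupted = arm_tab[arm_tab["disrupted"]]
        stable = arm_tab[~arm_tab["disrupted"]]

        entry: dict = {
            "n_segments": int(len(arm_tab)),
            "n_disrupted": int(len(disrupted)),
            "n_nondisrupted": int(len(stable)),
            "groups": {},
            "roc": {},
            "combination": None,
        }
        if len(disrupted):
            entry["groups"]["fer_disrupted"] = summarize_groups(disrupted["fer"])
        if len(stable):
            entry["groups"]["fer_nondisrupted"] = summarize_groups(stable["fer"])
        if len(disrupted) >= 2 and len(stable) >= 2:
            t, df, p = unpaired_t_test(disrupted["fer"], stable["fer"])
            entry["fer_t_test"] = {"t": t, "df": df, "p": p}
        if len(arm_open):
            entry["groups"]["openview_plaque"] = summarize_groups(
                arm_open["plaque_fer"]
            )
            entry["groups"]["openview_thrombus"] = summarize_groups(
                arm_open["thrombus_fer"]
            )
            if len(arm_open) >= 2:
                t, df, p = unpaired_t_test(
                    arm_open["plaque_fer"], arm_open["thrombus_fer"]
                )
                entry["openview_t_test"] = {"t": t, "df": df, "p": p}

        both_classes = len(disrupted) > 0 and len(stable) > 0
        if both_classes:
            labels = arm_tab["disrupted"].to_numpy(bool)
            for pred in predictors:
                entry["roc"][pred] = _roc_entry(arm_tab[pred].to_numpy(), labels)
            comb = optimize_combination(
                arm_tab[predictors].to_numpy(), labels, step_pct, predictors
            )
            entry["combination"] = {
                "predictors": comb.predictor_names,
                "step_pct": comb.step_pct,
                "best_weights": list(comb.best_weights),
                "best_auc": comb.best_auc,
                "best_auc_se": comb.best_roc.auc_se,
                "grid": [
                    {"weights": list(w), "auc": a} for w, a in comb.grid
                ],
            }
        report["arms"][probe] = entry
    return report


def _roc_summary_frame(report: dict) -> pd.DataFrame:
    """Human-readable per-arm summary of ROC results (one row per predictor
    and one for the optimized combination)."""
    rows = []
    for probe, arm in report["arms"].items():
        for pred, r in arm["roc"].items():
            rows.append(
                {
                    "probe": probe,
                    "predictor": pred,
                    "auc": r["auc"],
                    "auc_se": r["auc_se"],
                    "cutoff": r["cutoff"],
                    "sensitivity": r["sensitivity"],
                    "specificity": r["specificity"],
                    "failed": r["failed"],
                }
            )
        comb = arm["combination"]
        if comb:
            weights = ", ".join(
                f"{name}: {w * 100:.0f}%"
                for name, w in zip(comb["predictors"], comb["best_weights"])
            )
            rows.append(
                {
                    "probe": probe,
                    "predictor": f"combined ({weights})",
                    "auc": comb["best_auc"],
                    "auc_se": comb["best_auc_se"],
                    "cutoff": np.nan,
                    "sensitivity": np.nan,
                    "specificity": np.nan,
                    "failed": comb["best_auc"] < 0.5,
                }
            )
    return pd.DataFrame(rows)


def _merge_tables(data_dir: Path, out_dir: Path) -> pd.DataFrame:
    segments = pd.read_csv(data_dir / "segments.csv")
    fer = pd.read_csv(out_dir / "fer.csv")
    mri = pd.read_csv(out_dir / "mri_metrics.csv")
    table = (
        segments.merge(fer[["rabbit_id", "segment_index", "fer"]],
                       on=["rabbit_id", "segment_index"], how="left")
        .merge(mri, on=["rabbit_id", "segment_index"], how="left")
        .sort_values(["rabbit_id", "segment_index"])
        .reset_index(drop=True)
    )
    missing = table[PREDICTORS].isna().any(axis=1)
    if missing.any():
        raise RuntimeError(
            f"{int(missing.sum())} segments lack quantified predictors after the merge"
        )
    return table


def run_study(config: CohortConfig, seed: int, out_dir: str | Path) -> dict:
    """Execute simulate -> quantify -> classify and write all artifacts.

    Artifacts under ``out_dir``: ``data/`` (images, segments.csv,
    mri_slices.csv, config.yaml), ``fer.csv``, ``open_view.csv``,
    ``mri_metrics.csv``, ``analysis_table.csv``, ``roc_report.json``,
    ``combination_report.json``, ``roc_summary.csv`` and the full
    ``study_report.json``.  Returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config.with_seed(seed)

    log.info("simulate: seed=%d hash=%s", seed, config_hash(config))
    cohort = generate_cohort(config)
    data_dir = write_cohort(cohort, out / "data")

    log.info("quantify-fluor: %d rabbits", len(cohort.rabbits))
    _, open_view = quantify_directory(
        data_dir, out, config.axial_segment_length_mm
    )
    log.info("quantify-mri")
    quantify_mri_directory(data_dir, out, config.axial_segment_length_mm)

    table = _merge_tables(data_dir, out)
    table.to_csv(out / "analysis_table.csv", index=False)

    log.info("classify: %d segments", len(table))
    report = build_report(table, open_view)
    report["provenance"] = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "plaqrisk_version": __version__,
        "n_segments": int(len(table)),
        "n_disrupted": int(table["disrupted"].sum()),
        "n_nondisrupted": int((~table["disrupted"]).sum()),
    }

    (out / "roc_report.json").write_text(
        json.dumps(
            {p: {pred: a["roc"][pred] for pred in a["roc"]}
             for p, a in report["arms"].items()},
            indent=1, sort_keys=True,
        )
    )
    (out / "combination_report.json").write_text(
        json.dumps(
            {p: a["combination"] for p, a in report["arms"].items()},
            indent=1, sort_keys=True,
        )
    )
    _roc_summary_frame(report).to_csv(out / "roc_summary.csv", index=False)
    (out / "study_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report


def rebuild_report(out_dir: str | Path) -> dict:
    """Re-derive the report from the on-disk artifacts of a previous run.

    ``float_precision="round_trip"`` guarantees the CSV-parsed values equal
    the ones the pipeline wrote, so the rebuilt report matches bit for bit.
    """
    out = Path(out_dir)
    table = pd.read_csv(out / "analysis_table.csv", float_precision="round_trip")
    open_view = pd.read_csv(out / "open_view.csv", float_precision="round_trip")
    return build_report(table, open_view)
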