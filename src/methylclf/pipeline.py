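"""End-to-end orchestration of the discovery and replication arms.

``run_discovery`` chains probe filtering → batch adjustment → cell-type
estimation → DMP calling → DMR calling → nested LOOCV → recurrence ranking,
and writes a JSON+TSV report bundle. ``run_replication`` chains standard
curve → PMR → rank-sum group test → closest-top-left threshold. Every report
embeds the resolved configuration and content hashes of its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cellcomp, classify, dmp, dmr, methylight, preprocess, synthetic

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "alpha": 0.05,
    "min_abs_delta": 0.05,
    "nsc_delta": 1.0,
    "detection_rule": "any",
    "detection_p_threshold": 0.01,
    "bead_min": 3,
    "bead_sample_fraction": 0.05,
    "combat": True,
    "dmr": True,
    "loocv": True,
    "mds": True,
    "dilution_factor": 4.0,
    "n_discriminating": 600,
    "seed": 0,
}


def _content_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_json_default, sort_keys=True))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# input loading
# ---------------------------------------------------------------------------

def load_cohort_inputs(paths: dict[str, str | Path]):
    beta = pd.read_csv(paths["beta"], sep="\t", index_col=0)
    sheet = pd.read_csv(paths["sample_sheet"], index_col=0)
    annot = pd.read_csv(paths["annotation"], sep="\t", index_col=0)
    det = pd.read_csv(paths["detection_p"], sep="\t", index_col=0)
    beads = pd.read_csv(paths["bead_count"], sep="\t", index_col=0)
    reference = pd.read_csv(paths["cell_reference"], sep="\t", index_col=0)
    return beta, sheet, annot, det, beads, reference


# ---------------------------------------------------------------------------
# discovery arm
# ---------------------------------------------------------------------------

def run_discovery(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    annot: pd.DataFrame,
    detection_p: pd.DataFrame,
    bead_count: pd.DataFrame,
    cell_reference: pd.DataFrame | synthetic.CellReference,
    outdir: str | Path,
    params: dict[str, Any] | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> dict[str, Any]:
    """Run the discovery arm end to end; returns the report bundle dict."""
    cfg = dict(DEFAULT_PARAMS)
    if params:
        cfg.update(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    if input_paths:
        report["input_hashes"] = {k: _content_hash(v) for k, v in input_paths.items()}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("filter")
        filtered, filt_report = preprocess.filter_probes(
            beta,
            annot.loc[beta.index],
            detection_p,
            bead_count,
            detection_p_threshold=cfg["detection_p_threshold"],
            detection_rule=cfg["detection_rule"],
            bead_min=cfg["bead_min"],
            bead_sample_fraction=cfg["bead_sample_fraction"],
        )
        report["stages"]["filter"] = filt_report.to_dict()
        filtered.to_csv(outdir / "beta_filtered.tsv", sep="\t")
        _write_json(filt_report.to_dict(), outdir / "filter_report.json")

        if cfg["combat"] and sample_sheet["batch_id"].nunique() > 1:
            name = stage("batch_adjust")
            adjusted, _ = preprocess.combat_adjust(filtered, sample_sheet)
            report["stages"]["batch_adjust"] = {"n_batches": int(sample_sheet["batch_id"].nunique())}
        else:
            adjusted = filtered

        if cfg["mds"]:
            name = stage("mds")
            coords = preprocess.mds_embed(adjusted)
            coords.to_csv(outdir / "mds.csv")
            report["stages"]["mds"] = {"n_dims": coords.shape[1]}

        name = stage("cell_composition")
        if isinstance(cell_reference, synthetic.CellReference):
            ref_df = cell_reference.discriminating_values
        else:
            ref_df = cell_reference
        cells = cellcomp.estimate_cell_proportions(adjusted, ref_df)
        sheet_out = sample_sheet.join(cells)
        sheet_out.to_csv(outdir / "sample_sheet_with_cells.csv")
        report["stages"]["cell_composition"] = {"cell_types": list(cells.columns)}

        name = stage("dmp")
        stats_table, selected = dmp.run_dmp_analysis(
            adjusted,
            sample_sheet,
            cells,
            alpha=cfg["alpha"],
            min_abs_delta=cfg["min_abs_delta"],
            annot=annot,
        )
        dmp.dmp_table_for_export(selected).to_csv(outdir / "dmps.tsv", sep="\t", index=False)
        report["stages"]["dmp"] = {
            "n_tested": int(len(stats_table)),
            "n_selected": int(len(selected)),
            "d0": float(stats_table.attrs.get("d0", np.nan)),
        }

        if cfg["dmr"]:
            name = stage("dmr")
            dmr_params = dmr.DmrParams()
            probe_stats = stats_table.join(annot[["chrom", "pos", "feature", "cpg_context"]])
            probe_stats = probe_stats.sort_values(["chrom", "pos"], kind="mergesort")
            radii = dmr.compute_lasso_radii(probe_stats, dmr_params)
            dmrs = dmr.call_dmrs(probe_stats[["chrom", "pos", "p"]], radii, dmr_params)
            export = dmrs.copy()
            export["probe_ids"] = export["probe_ids"].map(";".join)
            export.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
            dmr.dmrs_to_bed(dmrs).to_csv(outdir / "dmrs.bed", sep="\t", index=False, header=False)
            report["stages"]["dmr"] = {"n_dmrs": int(len(dmrs))}

        if cfg["loocv"]:
            name = stage("loocv")
            loocv = classify.loocv_evaluate(
                adjusted,
                sample_sheet,
                cells,
                alpha=cfg["alpha"],
                min_abs_delta=cfg["min_abs_delta"],
                nsc_delta=cfg["nsc_delta"],
            )
            _write_json(loocv.to_dict(), outdir / "loocv.json")
            loocv.roc.to_csv(outdir / "roc.csv", index=False)
            ranked = classify.rank_dmp_recurrence(loocv, selected)
            ranked_cols = [c for c in ("rank", "recurrence", "p_bonferroni", "delta_beta",
                                       "chrom", "pos", "gene", "feature", "cpg_context")
                           if c in ranked.columns]
            ranked[ranked_cols].to_csv(outdir / "dmps_ranked.tsv", sep="\t")
            report["stages"]["loocv"] = {
                "auc": loocv.auc,
                "auc_ci": list(loocv.auc_ci),
                "n_iterations": loocv.n_iterations,
                "n_zero_dmp_folds": len(loocv.zero_dmp_folds),
            }
    except StageError:
        raise
    except Exception as exc:  # halt with the failing stage named
        raise StageError(name, exc) from exc

    _write_json(report, outdir / "discovery_report.json")
    return report


def discovery_analog(
    config: synthetic.CohortConfig,
    loocv: bool = True,
) -> dict[str, Any]:
    """In-memory discovery run on a synthetic cohort, scored against truth.

    Returns planted-DMP sensitivity/false discoveries and (optionally) the
    pooled nested-LOOCV AUC. Used by the acceptance checks.
    """
    beta, sheet, annot, qc, ref, truth = synthetic.simulate_cohort(config)
    filtered, _ = preprocess.filter_probes(beta, annot, qc.detection_p, qc.bead_count)
    if sheet["batch_id"].nunique() > 1:
        adjusted, _ = preprocess.combat_adjust(filtered, sheet)
    else:
        adjusted = filtered
    cells = cellcomp.estimate_cell_proportions(adjusted, ref)
    _, selected = dmp.run_dmp_analysis(adjusted, sheet, cells)
    planted = truth.planted_dmps.index
    out: dict[str, Any] = {
        "n_selected": int(len(selected)),
        "n_planted": int(len(planted)),
        "sensitivity": (
            len(selected.index.intersection(planted)) / len(planted) if len(planted) else np.nan
        ),
        "n_false": int(len(selected.index.difference(planted))),
        "truth": truth,
        "selected": selected,
        "adjusted": adjusted,
        "sheet": sheet,
        "cells": cells,
        "annot": annot,
    }
    if loocv:
        rep = classify.loocv_evaluate(adjusted, sheet, cells)
        out["auc"] = rep.auc
        out["auc_ci"] = rep.auc_ci
        out["loocv"] = rep
    return out


# ---------------------------------------------------------------------------
# replication arm
# ---------------------------------------------------------------------------

def run_replication(
    plate: pd.DataFrame,
    group_labels: pd.Series,
    outdir: str | Path,
    params: dict[str, Any] | None = None,
    positive_group: str = "severe",
    input_paths: dict[str, str | Path] | None = None,
) -> dict[str, Any]:
    """Run the MethyLight replication arm; returns the report bundle dict."""
    cfg = dict(DEFAULT_PARAMS)
    if params:
        cfg.update(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    if input_paths:
        report["input_hashes"] = {k: _content_hash(v) for k, v in input_paths.items()}

    name = "standard_curve"
    try:
        pmr_table, info = methylight.pmr_from_plate(
            plate, dilution_factor=cfg["dilution_factor"]
        )
        report["stages"]["standard_curve"] = {
            assay: dataclasses.asdict(curve) for assay, curve in info["curves"].items()
        }
        name = "pmr"
        pmr_table.to_csv(outdir / "pmr.csv")
        report["stages"]["pmr"] = {
            "n_samples": int(len(pmr_table)),
            "excluded_samples": info["excluded_samples"],
            "n_excluded": len(info["excluded_samples"]),
        }

        name = "group_test"
        labels = group_labels.reindex(pmr_table.index)
        usable = pmr_table["pmr"].notna() & labels.notna()
        values = pmr_table.loc[usable, "pmr"]
        is_pos = labels[usable].astype(str) == positive_group
        grp_pos = values[is_pos].to_numpy()
        grp_neg = values[~is_pos].to_numpy()
        u, p = methylight.wilcoxon_rank_sum(grp_pos, grp_neg)
        report["stages"]["group_test"] = {
            "u_statistic": u,
            "p_two_sided": p,
            "group_medians": {
                positive_group: float(np.median(grp_pos)),
                "other": float(np.median(grp_neg)),
            },
        }

        name = "threshold"
        thr = methylight.closest_topleft_threshold(values.to_numpy(), is_pos.astype(int).to_numpy())
        report["stages"]["threshold"] = dataclasses.asdict(thr)
    except Exception as exc:
        raise StageError(name, exc) from exc

    _write_json(report, outdir / "replication_report.json")
    return report
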