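"""End-to-end driver: simulate -> map -> count -> activity -> skew ->
response -> nominate, with truth-based evaluation metrics.

``run_pipeline`` executes the full chain on a simulated experiment defined
by a :class:`~mprakit.io.PipelineConfig`, optionally writes every stage
output plus a manifest, and returns the result bundle in memory.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import child_rng
from .activity import element_activity, test_activity
from .barcodes import BarcodeAssignment, aggregate_counts
from .io import PipelineConfig, write_json, write_tsv
from .response import element_response, test_response, zscore_matrix
from .samples import default_sample_sheet, rna_samples
from .simulate import (TruthTable, simulate_barcode_map, simulate_counts,
                       simulate_library, simulate_truth)
from .skew import log_ratios, merge_conditions, snp_skew_summary, test_skew
from .nominate import annotate_candidates, group_by_signal, nominate

__all__ = ["ld_table_from_library", "run_pipeline", "skew_metrics",
           "activity_metrics", "nomination_metrics"]


def ld_table_from_library(library: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Derive the LD membership table implied by a simulated library: one
    signal per T2D signal_id, first member as index SNP (r^2 = 1), the rest
    with r^2 drawn uniformly on [0.8, 1]."""
    rng = child_rng(seed, "ld")
    t2d = library[library["category"] == "T2D"]
    rows = []
    for signal_id, grp in t2d.groupby("signal_id", sort=True):
        snps = sorted({s for row in grp["snp_ids"] for s in row.split(",")})
        for i, snp in enumerate(snps):
            r2 = 1.0 if i == 0 else float(rng.uniform(0.8, 1.0))
            rows.append((snp, signal_id, r2, i == 0))
    return pd.DataFrame(rows, columns=["snp_id", "signal_id", "r2", "is_index"])


def activity_metrics(activity: pd.DataFrame, truth: TruthTable) -> dict:
    """Oligo-level sensitivity / empirical FDR of active calls vs truth."""
    t = truth.oligos.set_index("oligo_id")["activity_log2fc"]
    act = activity.set_index("oligo_id")
    truly = t > 0
    called = act["active"].reindex(t.index).fillna(False).astype(bool)
    n_true, n_called = int(truly.sum()), int(called.sum())
    sens = float((called & truly).sum() / n_true) if n_true else float("nan")
    fdr = float((called & ~truly).sum() / n_called) if n_called else 0.0
    return {"sensitivity": sens, "fdr": fdr, "n_true": n_true, "n_called": n_called}


def skew_metrics(skew_summary: pd.DataFrame, truth: TruthTable) -> dict:
    """SNP-level skew sensitivity, empirical FDR, and direction accuracy."""
    t = truth.snps.set_index("snp_id")
    s = skew_summary.set_index("snp_id")
    detected = s.index[s["skew"].astype(bool)]
    truly = set(t.index[t["true_skew"].astype(bool)])
    n_det = len(detected)
    tp = [snp for snp in detected if snp in truly]
    sens = len(tp) / len(truly) if truly else float("nan")
    fdr = (n_det - len(tp)) / n_det if n_det else 0.0
    correct_dir = sum(1 for snp in tp
                      if s.at[snp, "direction"] == t.at[snp, "true_direction"])
    dir_acc = correct_dir / len(tp) if tp else float("nan")
    return {"sensitivity": float(sens), "fdr": float(fdr),
            "direction_accuracy": float(dir_acc),
            "n_true": len(truly), "n_detected": n_det}


def nomination_metrics(signals: pd.DataFrame, truth: TruthTable,
                       ld_table: pd.DataFrame) -> dict:
    """Among detected-functional signals: single-candidate classification
    rate, and how often the signal's true causal SNP is among candidates."""
    truly_skewed = set(truth.snps.loc[truth.snps["true_skew"], "snp_id"])
    causal_by_signal = (ld_table[ld_table["snp_id"].isin(truly_skewed)]
                        .groupby("signal_id")["snp_id"].apply(set).to_dict())
    functional = signals[signals["n_skew"] > 0]
    n_func = len(functional)
    single = int((functional["class"] == "single_candidate").sum())
    hit = 0
    evaluable = 0
    for _, row in functional.iterrows():
        causal = causal_by_signal.get(row["signal_id"], set())
        if not causal:
            continue
        evaluable += 1
        if causal & set(row["candidates"].split(",")):
            hit += 1
    return {
        "n_functional": n_func,
        "single_candidate_rate": single / n_func if n_func else float("nan"),
        "causal_identity_accuracy": hit / evaluable if evaluable else float("nan"),
        "n_evaluable": evaluable,
    }


def run_pipeline(config: PipelineConfig, out_dir=None,
                 conditions: tuple[str, ...] = ("standard", "dmso", "tg")) -> dict:
    """Run the full simulated pipeline; returns the result bundle.

    When ``out_dir`` is given, every stage output is written as TSV plus a
    ``manifest.json`` recording the configuration, seeds, versions, and row
    counts, and a ``summary.json`` with headline counts and truth metrics.
    Identical config (and seed) reproduces byte-identical outputs.
    """
    cfg = config
    library = simulate_library(cfg.n_elements, cfg.category_props, cfg.n_signals,
                               cfg.frac_two_snp, seed=cfg.seed)
    truth = simulate_truth(library, frac_active=cfg.frac_active,
                           activity_log2fc=cfg.activity_log2fc,
                           frac_skew=cfg.frac_skew,
                           allelic_effect_log2=cfg.allelic_effect_log2,
                           frac_higher=cfg.frac_higher, frac_lower=cfg.frac_lower,
                           condition_log2fc=cfg.condition_log2fc,
                           alpha_range=cfg.alpha_range, seed=cfg.seed)
    bcmap = simulate_barcode_map(library, cfg.barcodes_per_oligo,
                                 cfg.ambiguous_rate, seed=cfg.seed)
    samples = default_sample_sheet(cfg.n_rna_replicates, cfg.n_dna_replicates,
                                   conditions=conditions)
    bc_counts = simulate_counts(library, bcmap, truth, samples,
                                depth=cfg.depth,
                                dna_dispersion=cfg.dna_dispersion,
                                seed=cfg.seed)
    assignment = BarcodeAssignment.from_frame(bcmap)
    counts, n_barcodes = aggregate_counts(bc_counts, assignment,
                                          oligo_ids=list(library["oligo_id"]))

    activity_frames, skew_frames, ratio_frames = [], {}, {}
    for cond in conditions:
        act = test_activity(counts, samples, cond, fdr=cfg.fdr_activity,
                            shrink=cfg.dispersion_shrink,
                            one_sided=cfg.one_sided_activity,
                            fdr_method=cfg.fdr_method)
        activity_frames.append(act)
        ratios = log_ratios(counts, samples, cond, pseudocount=cfg.pseudocount)
        ratio_frames[cond] = ratios
        skew_frames[cond] = test_skew(ratios, library, act, cond, fdr=cfg.fdr_skew)
    activity = pd.concat(activity_frames, ignore_index=True)
    elements_active = element_activity(activity, library)
    merged_skew = (merge_conditions(skew_frames) if len(skew_frames) >= 2
                   else snp_skew_summary(next(iter(skew_frames.values()))))
    skew_by_condition = pd.concat([snp_skew_summary(f) for f in skew_frames.values()],
                                  ignore_index=True)

    bundle: dict = {
        "config": cfg, "library": library, "truth": truth, "barcode_map": bcmap,
        "samples": samples, "barcode_counts": bc_counts, "counts": counts,
        "n_barcodes_observed": n_barcodes, "activity": activity,
        "elements_active": elements_active, "skew": skew_frames,
        "merged_skew": merged_skew, "skew_by_condition": skew_by_condition,
        "ratios": ratio_frames,
    }

    if "dmso" in conditions and "tg" in conditions:
        response = test_response(ratio_frames["dmso"], ratio_frames["tg"],
                                 fdr=cfg.fdr_response)
        both = pd.concat([ratio_frames["dmso"], ratio_frames["tg"]], axis=1)
        zscores, constant_rows = zscore_matrix(both)
        bundle["response"] = response
        bundle["elements_response"] = element_response(response, library)
        bundle["zscores"] = zscores
        bundle["constant_rows"] = constant_rows

    ld = ld_table_from_library(library, seed=cfg.seed)
    if len(ld):
        skeleton = group_by_signal(library, ld, r2_min=cfg.r2_min)
        signals, signal_summary = nominate(skeleton, merged_skew)
        candidates = annotate_candidates(signals, skew_by_condition)
        bundle.update({"ld_table": ld, "signals": signals,
                       "signal_summary": signal_summary, "candidates": candidates})

    summary = {
        "n_elements": int(library["element_id"].nunique()),
        "n_oligos": int(len(library)),
        "n_barcodes": int(len(bcmap)),
        "n_ambiguous_barcodes": int(bcmap["ambiguous"].sum()) if len(bcmap) else 0,
        "active_oligos_by_condition": {
            c: int(activity.loc[activity["condition"] == c, "active"].sum())
            for c in conditions},
        "active_elements_any_condition": int(
            elements_active.drop_duplicates("element_id")["active_any_condition"].sum()),
        "skew_snps_any_condition": int(len(merged_skew)),
        "activity_metrics": activity_metrics(
            activity[activity["condition"] == conditions[0]], truth),
        "skew_metrics": skew_metrics(
            merged_skew.assign(skew=True) if "skew" not in merged_skew.columns
            else merged_skew, truth),
    }
    if "response" in bundle:
        summary["response_counts"] = (
            bundle["response"]["response"].value_counts().to_dict())
    if "signals" in bundle:
        summary["signal_summary"] = bundle["signal_summary"]
        summary["nomination_metrics"] = nomination_metrics(
            bundle["signals"], truth, ld)
    bundle["summary"] = summary

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg: PipelineConfig = bundle["config"]
    write_tsv(bundle["library"], out / "library.tsv", index=False)
    write_tsv(bundle["truth"].oligos, out / "truth_oligos.tsv", index=False)
    write_tsv(bundle["truth"].snps, out / "truth_snps.tsv", index=False)
    write_tsv(bundle["truth"].elements, out / "truth_elements.tsv", index=False)
    write_tsv(bundle["barcode_map"], out / "barcode_map.tsv", index=False)
    write_tsv(bundle["samples"], out / "sample_sheet.tsv", index=False)
    write_tsv(bundle["barcode_counts"], out / "barcode_counts.tsv")
    write_tsv(bundle["counts"], out / "oligo_counts.tsv")
    write_tsv(bundle["activity"], out / "activity.tsv", index=False)
    for cond, frame in bundle["skew"].items():
        write_tsv(frame, out / f"skew_{cond}.tsv", index=False)
    write_tsv(bundle["merged_skew"], out / "skew_merged.tsv", index=False)
    if "response" in bundle:
        write_tsv(bundle["response"], out / "response.tsv", index=False)
        write_tsv(bundle["zscores"], out / "zscores.tsv")
    if "signals" in bundle:
        write_tsv(bundle["signals"], out / "signals.tsv", index=False)
        write_tsv(bundle["candidates"], out / "candidates.tsv", index=False)
    write_json(bundle["summary"], out / "summary.json")
    manifest = {
        "mprakit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "rows": {
            "library": int(len(bundle["library"])),
            "barcode_map": int(len(bundle["barcode_map"])),
            "counts": int(len(bundle["counts"])),
            "activity": int(len(bundle["activity"])),
        },
    }
    write_json(manifest, out / "manifest.json")
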