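"""Reference simulation studies: null calibration, parameter recovery, and
end-to-end nomination on planted single-causal signals.

These encode the package's reference study conditions:

* ``null_calibration`` — a fully null library (no activity, no allelic
  effects, no stress response) of 2,000 oligos with one plasmid and five RNA
  replicates per condition, one barcode per oligo (so the per-oligo
  dispersion, uniform on [0.05, 0.5], is the oligo-level dispersion), at a
  mean depth of 200 reads per oligo.  Measures the fraction of q<1% active
  calls and q<10% skew calls.
* ``parameter_recovery`` — planted activity β = 1.5 log2 and allelic skew
  Δ = 1 log2 at base mean ≈ 200, 5 RNA replicates, the multi-barcode
  generative model (30 barcodes/oligo) and five technical plasmid
  replicates (deep plasmid measurement, which the paired-ratio skew test
  requires for calibration).
* ``end_to_end_nomination`` — a T2D-style library grouped into GWAS signals
  with exactly one causal (skewed, Δ = 1.5 log2) SNP planted per signal;
  runs the full pipeline across all three conditions and scores the
  single-candidate classification rate and causal-identity accuracy among
  detected-functional signals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_seed
from .activity import test_activity
from .barcodes import BarcodeAssignment, aggregate_counts
from .pipeline import (activity_metrics, group_by_signal, ld_table_from_library,
                       nominate, nomination_metrics, skew_metrics)
from .samples import default_sample_sheet
from .simulate import (simulate_barcode_map, simulate_counts, simulate_library,
                       simulate_truth)
from .skew import log_ratios, merge_conditions, snp_skew_summary, test_skew

__all__ = ["end_to_end_nomination", "null_calibration", "parameter_recovery"]

CONDITIONS = ("standard", "dmso", "tg")


def _aggregate(lib, bcmap, counts_bc):
    asg = BarcodeAssignment.from_frame(bcmap)
    counts, _ = aggregate_counts(counts_bc, asg, oligo_ids=list(lib["oligo_id"]))
    return counts


def null_calibration(seeds=range(10), n_oligos: int = 2000,
                     depth_per_oligo: float = 200.0) -> dict:
    """Fraction of active calls (q<1%) and skew calls (q<10%) on fully null
    simulations, averaged over seeds."""
    active_flagged = active_tested = 0
    skew_flagged = skew_tested = 0
    for seed in seeds:
        lib = simulate_library(n_oligos // 2, category_props=(0.0, 0.5, 0.5),
                               n_signals=1, frac_two_snp=0.0, seed=seed)
        truth = simulate_truth(lib, frac_active=0.0, frac_skew=0.0,
                               frac_higher=0.0, frac_lower=0.0,
                               alpha_range=(0.05, 0.5), seed=seed)
        bcmap = simulate_barcode_map(lib, barcodes_per_oligo=1, seed=seed)
        samples = default_sample_sheet(n_rna=5, n_dna=1)
        counts_bc = simulate_counts(lib, bcmap, truth, samples,
                                    depth=depth_per_oligo * len(lib), seed=seed)
        counts = _aggregate(lib, bcmap, counts_bc)
        from .skew import snp_contrasts
        n_contrasts = len(snp_contrasts(lib))
        for cond in CONDITIONS:
            act = test_activity(counts, samples, cond)
            active_flagged += int(act["active"].sum())
            active_tested += int(act["tested"].sum())
            rho = log_ratios(counts, samples, cond)
            sk = test_skew(rho, lib, act, cond)
            skew_flagged += int(sk["skew"].sum()) if len(sk) else 0
            # denominator: every allelic contrast the library defines — on a
            # null library almost none become eligible, and the scientific
            # question is how many of the library's SNPs get falsely reported
            skew_tested += n_contrasts
    return {
        "active_call_fraction": active_flagged / active_tested,
        "skew_call_fraction": (skew_flagged / skew_tested) if skew_tested else 0.0,
        "n_active_tested": active_tested,
        "n_skew_tested": skew_tested,
    }


def parameter_recovery(seed: int = 0, n_elements: int = 250,
                       activity_log2fc: float = 1.5,
                       allelic_effect_log2: float = 1.0,
                       depth_per_oligo: float = 250.0) -> dict:
    # nominal depth 250/oligo: softmax renormalization against the active
    # half of the library brings the realized median base mean to ~200
    """Activity and skew recovery at the reference effect sizes."""
    lib = simulate_library(n_elements, category_props=(0.0, 0.5, 0.5),
                           n_signals=1, frac_two_snp=0.1, seed=seed)
    truth = simulate_truth(lib, frac_active=0.5, activity_log2fc=activity_log2fc,
                           frac_skew=0.5, allelic_effect_log2=allelic_effect_log2,
                           alpha_range=(0.05, 0.5), seed=seed)
    bcmap = simulate_barcode_map(lib, barcodes_per_oligo=30, seed=seed)
    samples = default_sample_sheet(n_rna=5, n_dna=5, conditions=("standard",))
    counts_bc = simulate_counts(lib, bcmap, truth, samples,
                                depth=depth_per_oligo * len(lib), seed=seed)
    counts = _aggregate(lib, bcmap, counts_bc)
    act = test_activity(counts, samples, "standard")
    rho = log_ratios(counts, samples, "standard")
    sk = test_skew(rho, lib, act, "standard")
    summ = snp_skew_summary(sk)
    am = activity_metrics(act, truth)
    sm = skew_metrics(summ, truth)
    return {
        "activity_sensitivity": am["sensitivity"],
        "activity_fdr": am["fdr"],
        "skew_sensitivity": sm["sensitivity"],
        "skew_fdr": sm["fdr"],
        "skew_direction_accuracy": sm["direction_accuracy"],
        "base_mean_median": float(act["base_mean"].median()),
        "n_true_skew": sm["n_true"],
    }


def end_to_end_nomination(seed: int = 0, n_signals: int = 50,
                          n_elements: int = 300,
                          allelic_effect_log2: float = 1.5,
                          depth_per_oligo: float = 200.0) -> dict:
    """Full pipeline on a T2D-style library with one planted causal SNP per
    signal; scores nomination quality and headline activity counts."""
    lib = simulate_library(n_elements, category_props=(0.8, 0.1, 0.1),
                          n_signals=n_signals, frac_two_snp=0.05, seed=seed)
    ld = ld_table_from_library(lib, seed=seed)
    # plant exactly one causal SNP per signal: the index SNP's proxy set is
    # arbitrary, so take each signal's first member
    causal = (ld.sort_values(["signal_id", "snp_id"])
              .groupby("signal_id")["snp_id"].first().tolist())
    truth = simulate_truth(lib, frac_active=0.35, activity_log2fc=1.5,
                           allelic_effect_log2=allelic_effect_log2,
                           frac_higher=0.05, frac_lower=0.05,
                           alpha_range=(0.05, 0.5),
                           skew_snps=causal, seed=seed)
    bcmap = simulate_barcode_map(lib, barcodes_per_oligo=30,
                                 ambiguous_rate=0.02, seed=seed)
    samples = default_sample_sheet(n_rna=5, n_dna=5)
    counts_bc = simulate_counts(lib, bcmap, truth, samples,
                                depth=depth_per_oligo * len(lib), seed=seed)
    counts = _aggregate(lib, bcmap, counts_bc)
    skew_frames = {}
    n_active_oligos = {}
    active_elements = set()
    for cond in CONDITIONS:
        act = test_activity(counts, samples, cond)
        n_active_oligos[cond] = int(act["active"].sum())
        lib_ix = lib.set_index("oligo_id")["element_id"]
        active_elements |= set(lib_ix[act.loc[act["active"], "oligo_id"]].unique())
        rho = log_ratios(counts, samples, cond)
        skew_frames[cond] = test_skew(rho, lib, act, cond)
    merged = merge_conditions(skew_frames)
    skeleton = group_by_signal(lib, ld)
    signals, summary = nominate(skeleton, merged)
    nm = nomination_metrics(signals, truth, ld)
    sm = skew_metrics(merged.assign(skew=True), truth)
    truly_active = int(truth.elements["true_active"].sum())
    return {
        "single_candidate_rate": nm["single_candidate_rate"],
        "causal_identity_accuracy": nm["causal_identity_accuracy"],
        "n_functional_signals": nm["n_functional"],
        "n_signals": summary["n_signals"],
        "skew_sensitivity": sm["sensitivity"],
        "skew_fdr": sm["fdr"],
        "active_element_fraction": len(active_elements) / lib["element_id"].nunique(),
        "true_active_element_fraction": truly_active / lib["element_id"].nunique(),
        "n_skew_snps": int(len(merged)),
    }


def derived_seed(root: int, label: str) -> int:
    """Stable child seed for one benchmark stage (kept below 2^31)."""
    return child_seed(root, "benchmark", label)
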