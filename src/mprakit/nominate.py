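"""Roll allelic-skew calls up to GWAS association signals.

A signal groups an index SNP with its LD proxies (r^2 >= 0.8).  A member
SNP is "functional" for the signal if it shows allelic skew in at least one
experimental condition (union semantics).  Signals are then classified by
candidate multiplicity: none / single_candidate / two_candidates /
multi_candidate — single-candidate signals are the headline outcome, since
they nominate one putative causal variant for the locus.  Signals with
overlapping LD blocks are kept distinct; a shared SNP contributes to each.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["annotate_candidates", "classify_count", "group_by_signal", "nominate"]


def classify_count(n_skew: int) -> str:
    if n_skew == 0:
        return "none"
    if n_skew == 1:
        return "single_candidate"
    if n_skew == 2:
        return "two_candidates"
    return "multi_candidate"


def group_by_signal(library: pd.DataFrame, ld_table: pd.DataFrame,
                    r2_min: float = 0.8) -> pd.DataFrame:
    """Build the per-signal skeleton from the library and an LD table.

    ``ld_table`` columns: snp_id, signal_id, r2, is_index.  Members below
    ``r2_min`` are rejected with a warning; duplicated membership rows
    collapse.  Every T2D SNP in the library must carry a signal assignment,
    otherwise the offenders are listed in the error.
    """
    required = {"snp_id", "signal_id", "r2"}
    missing = required - set(ld_table.columns)
    if missing:
        raise ValueError(f"LD table missing columns: {sorted(missing)}")
    ld = ld_table.drop_duplicates(["snp_id", "signal_id"]).copy()
    low = ld["r2"] < r2_min
    if low.any():
        warnings.warn(f"rejecting {int(low.sum())} LD members with r2 < {r2_min}")
        ld = ld[~low]

    t2d = library[library["category"] == "T2D"]
    t2d_snps: set[str] = set()
    for s in t2d["snp_ids"]:
        t2d_snps.update(s.split(","))
    covered = set(ld["snp_id"])
    orphans = sorted(t2d_snps - covered)
    if orphans:
        raise ValueError(f"T2D SNPs without a signal assignment: {orphans[:10]}"
                         + ("..." if len(orphans) > 10 else ""))

    rows = []
    for signal_id, grp in ld.groupby("signal_id", sort=True):
        members = sorted(set(grp["snp_id"]) & t2d_snps) or sorted(set(grp["snp_id"]))
        index_snp = ""
        if "is_index" in grp.columns:
            idx = grp.loc[grp["is_index"].astype(bool), "snp_id"]
            index_snp = idx.iloc[0] if len(idx) else ""
        rows.append((signal_id, index_snp, ",".join(members), len(members)))
    return pd.DataFrame(rows, columns=["signal_id", "index_snp", "members", "n_tested"])


def nominate(signals: pd.DataFrame, merged_skew: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Count functional member SNPs per signal and classify.

    ``merged_skew`` is the cross-condition union table (one row per SNP with
    skew in >=1 condition).  Returns the completed signal table plus a
    summary dict {n_signals, n_signals_functional, n_single_candidate,
    n_two_candidate, n_multi}.  Stable under permutation of input rows and
    idempotent.
    """
    skew_snps = set(merged_skew["snp_id"]) if len(merged_skew) else set()
    out = signals.sort_values("signal_id", kind="stable").reset_index(drop=True).copy()
    n_skew, candidates, classes = [], [], []
    for _, row in out.iterrows():
        members = row["members"].split(",") if row["members"] else []
        cand = sorted(m for m in members if m in skew_snps)
        n_skew.append(len(cand))
        candidates.append(",".join(cand))
        classes.append(classify_count(len(cand)))
    out["n_skew"] = n_skew
    out["candidates"] = candidates
    out["class"] = classes
    summary = {
        "n_signals": int(len(out)),
        "n_signals_functional": int((out["n_skew"] > 0).sum()),
        "n_single_candidate": int((out["class"] == "single_candidate").sum()),
        "n_two_candidate": int((out["class"] == "two_candidates").sum()),
        "n_multi": int((out["class"] == "multi_candidate").sum()),
    }
    return out, summary


def annotate_candidates(signals: pd.DataFrame,
                        skew_by_condition: pd.DataFrame,
                        annotations: pd.DataFrame | None = None,
                        caqtl: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-candidate report: index status, fine-mapping PPA, caQTL direction
    concordance, repeat class, and condition-specificity labels.

    ``skew_by_condition`` has one row per (snp_id, condition) with ``skew``
    and ``mean_diff_log2`` (the per-SNP summaries of each condition's skew
    results).  Two specificity labels are emitted: ``tg_not_standard``
    (skew in Tg but not under standard culture) and ``tg_only`` (skew
    exclusively in Tg).  Unresolvable annotation keys leave nulls with a
    warning rather than dropping the candidate.
    """
    cond_skew: dict[str, set[str]] = {}
    for cond, grp in skew_by_condition.groupby("condition"):
        cond_skew[cond] = set(grp.loc[grp["skew"], "snp_id"])
    direction = (skew_by_condition[skew_by_condition["skew"]]
                 .groupby("snp_id")["mean_diff_log2"].mean())

    ann = annotations.set_index("snp_id") if annotations is not None else None
    caq = caqtl.set_index("snp_id") if caqtl is not None else None
    unresolved = []
    rows = []
    for _, sig in signals.iterrows():
        for snp in (sig["candidates"].split(",") if sig.get("candidates") else []):
            in_tg = snp in cond_skew.get("tg", set())
            in_dmso = snp in cond_skew.get("dmso", set())
            in_std = snp in cond_skew.get("standard", set())
            rec = {
                "signal_id": sig["signal_id"],
                "snp_id": snp,
                "is_index": snp == sig.get("index_snp", ""),
                "mpra_direction_log2": float(direction.get(snp, np.nan)),
                "skew_standard": in_std,
                "skew_dmso": in_dmso,
                "skew_tg": in_tg,
                "tg_not_standard": in_tg and not in_std,
                "tg_only": in_tg and not in_dmso and not in_std,
                "ppa": np.nan,
                "repeat_class": "",
                "caqtl_beta": np.nan,
                "caqtl_concordant": pd.NA,
            }
            if ann is not None:
                if snp in ann.index:
                    rec["ppa"] = float(ann.at[snp, "ppa"]) if "ppa" in ann.columns else np.nan
                    if "repeat_class" in ann.columns:
                        rec["repeat_class"] = str(ann.at[snp, "repeat_class"] or "")
                else:
                    unresolved.append(snp)
            if caq is not None and snp in caq.index:
                beta = float(caq.at[snp, "beta"])
                rec["caqtl_beta"] = beta
                mpra = rec["mpra_direction_log2"]
                if np.isfinite(mpra) and beta != 0:
                    rec["caqtl_concordant"] = bool(np.sign(beta) == np.sign(mpra))
            rows.append(rec)
    if unresolved:
        warnings.warn(f"{len(unresolved)} candidate SNPs missing from annotations "
                      f"(e.g. {unresolved[0]!r}); rows kept with nulls")
    return pd.DataFrame(rows)
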