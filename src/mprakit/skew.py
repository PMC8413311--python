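"""Allelic skew: paired t-tests on log2 mRNA/plasmid ratios between the two
alleles of a SNP, restricted to sequences with significant MPRA activity,
at an FDR of 10%.

For each RNA replicate r the ratio is

    rho_ir = log2((K_ir / s_r + c) / (D_i + c))

where D_i is the batch's normalized plasmid profile (mean over the batch's
DNA samples of K/s) and c a pseudocount (default 1 normalized unit) keeping
zero counts finite.  The paired test compares rho(alt) - rho(ref) across
replicates.  For two-SNP elements each SNP is tested twice, once within
each fixed background allele of the other SNP (the four-combination
design); each contrast is an independent row entering BH, and a SNP shows
skew if any of its contrasts is significant.

Direction convention: positive mean difference = alternate allele more
active ("alt_up").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .activity import bh_adjust, size_factors
from .samples import condition_batch, dna_samples, rna_samples, validate_sample_sheet

__all__ = [
    "log_ratios",
    "merge_conditions",
    "paired_t",
    "snp_contrasts",
    "test_skew",
]


def log_ratios(counts: pd.DataFrame, samples: pd.DataFrame, condition: str,
               pseudocount: float = 1.0, sf: pd.Series | None = None) -> pd.DataFrame:
    """Per-oligo log2 mRNA/plasmid ratio matrix for one condition.

    Columns are the condition's RNA replicate sample ids; the denominator is
    the batch plasmid profile.  ``pseudocount`` must be positive.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    validate_sample_sheet(samples)
    batch = condition_batch(condition)
    dna_cols = dna_samples(samples, batch)
    rna_cols = rna_samples(samples, condition)
    if not dna_cols:
        raise ValueError(f"no plasmid sample for batch {batch}")
    if sf is None:
        sf = size_factors(counts[dna_cols + rna_cols])
    # anchor the factors to the plasmid profile: the pseudocount is then in
    # plasmid-scale units and rescaling any RNA replicate is absorbed exactly
    sf = sf / np.exp(np.log(sf[dna_cols]).mean())
    dna_norm = (counts[dna_cols] / sf[dna_cols]).mean(axis=1)
    out = {}
    for col in rna_cols:
        out[col] = np.log2((counts[col] / sf[col] + pseudocount)
                           / (dna_norm + pseudocount))
    return pd.DataFrame(out, index=counts.index)


def paired_t(diffs: np.ndarray) -> tuple[float, float, int, bool]:
    """Two-sided paired t-test from per-replicate differences.

    Returns (t, p, df, degenerate).  Conventions for zero-variance input:
    all differences exactly 0 -> t=0, p=1; identical nonzero differences ->
    sd treated as machine epsilon, p ~ 0, flagged degenerate.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t needs >=2 replicate differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, df, False
        t = np.sign(mean) / np.finfo(float).eps
        return float(t), 0.0, df, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df, False


def snp_contrasts(library: pd.DataFrame) -> pd.DataFrame:
    """Enumerate allelic contrasts: one per SNP for single-SNP elements, two
    per SNP (one per background allele of the partner SNP) for two-SNP
    elements.  Returns columns snp_id, element_id, background, ref_oligo,
    alt_oligo."""
    rows = []
    for element_id, grp in library.groupby("element_id", sort=True):
        combos = dict(zip(grp["allele_combo"], grp["oligo_id"]))
        snps = grp["snp_ids"].iloc[0].split(",")
        if len(snps) == 1:
            if "R" in combos and "A" in combos:
                rows.append((snps[0], element_id, "", combos["R"], combos["A"]))
            continue
        for k, snp in enumerate(snps):
            other = 1 - k
            for bg in "RA":
                ref_combo = ["", ""]
                alt_combo = ["", ""]
                ref_combo[k], alt_combo[k] = "R", "A"
                ref_combo[other] = alt_combo[other] = bg
                rc, ac = "".join(ref_combo), "".join(alt_combo)
                if rc in combos and ac in combos:
                    rows.append((snp, element_id, f"{snps[other]}:{bg}",
                                 combos[rc], combos[ac]))
    return pd.DataFrame(rows, columns=["snp_id", "element_id", "background",
                                       "ref_oligo", "alt_oligo"])


def test_skew(ratios: pd.DataFrame, library: pd.DataFrame,
              activity: pd.DataFrame, condition: str,
              fdr: float = 0.10) -> pd.DataFrame:
    """Test every eligible allelic contrast in one condition.

    A contrast is eligible when at least one of its two sequences is MPRA
    active in this condition.  BH is applied within the condition over the
    tested contrasts only.  Requires >=3 RNA replicates (paired df >= 2).

    Returns columns: snp_id, element_id, condition, background,
    mean_diff_log2, t, df, pvalue, qvalue, skew, direction, degenerate.
    """
    if ratios.shape[1] < 3:
        raise ValueError("skew testing needs >=3 RNA replicates")
    act = activity[activity["condition"] == condition]
    active = dict(zip(act["oligo_id"], act["active"]))
    contrasts = snp_contrasts(library)
    rows = []
    for _, c in contrasts.iterrows():
        if not (active.get(c["ref_oligo"], False) or active.get(c["alt_oligo"], False)):
            continue
        d = (ratios.loc[c["alt_oligo"]] - ratios.loc[c["ref_oligo"]]).to_numpy()
        t, p, df, degenerate = paired_t(d)
        rows.append((c["snp_id"], c["element_id"], condition, c["background"],
                     float(np.mean(d)), t, df, p, degenerate))
    out = pd.DataFrame(rows, columns=["snp_id", "element_id", "condition",
                                      "background", "mean_diff_log2", "t",
                                      "df", "pvalue", "degenerate"])
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
        out["skew"] = out["qvalue"] < fdr
        out["direction"] = np.where(out["mean_diff_log2"] > 0, "alt_up", "ref_up")
    else:
        out["qvalue"] = pd.Series(dtype=float)
        out["skew"] = pd.Series(dtype=bool)
        out["direction"] = pd.Series(dtype=object)
    cols = ["snp_id", "element_id", "condition", "background", "mean_diff_log2",
            "t", "df", "pvalue", "qvalue", "skew", "direction", "degenerate"]
    return out[cols]


def snp_skew_summary(skew: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP roll-up within one condition: skew if any contrast is
    significant; direction and mean difference taken from the smallest-p
    contrast."""
    if not len(skew):
        return pd.DataFrame(columns=["snp_id", "condition", "skew",
                                     "mean_diff_log2", "direction"])
    best = (skew.sort_values(["pvalue", "background"], kind="stable")
            .groupby(["snp_id", "condition"], as_index=False).first())
    any_skew = (skew.groupby(["snp_id", "condition"])["skew"].any()
                .rename("skew_any").reset_index())
    out = best.merge(any_skew, on=["snp_id", "condition"])
    out["skew"] = out["skew_any"]
    return out[["snp_id", "condition", "skew", "mean_diff_log2", "direction"]]


def merge_conditions(skew_results: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Union of SNPs with skew in >=1 condition, with cross-condition
    direction concordance.

    For SNPs skewed in >=2 conditions, ``concordant`` is True iff the signs
    of their per-condition mean differences all agree; it is NA for SNPs
    skewed in a single condition.  Symmetric in condition labels.
    """
    frames = list(skew_results.values()) if isinstance(skew_results, dict) else list(skew_results)
    if len(frames) < 2:
        raise ValueError("merge_conditions needs results from >=2 conditions")
    per_cond = pd.concat([snp_skew_summary(f) for f in frames], ignore_index=True)
    skewed = per_cond[per_cond["skew"]]
    rows = []
    for snp_id, grp in skewed.groupby("snp_id", sort=True):
        conds = sorted(grp["condition"])
        signs = np.sign(grp["mean_diff_log2"].to_numpy())
        concordant = bool((signs == signs[0]).all()) if len(grp) >= 2 else pd.NA
        rows.append((snp_id, len(grp), ",".join(conds), concordant,
                     grp["mean_diff_log2"].mean(),
                     "alt_up" if grp["mean_diff_log2"].mean() > 0 else "ref_up"))
    return pd.DataFrame(rows, columns=["snp_id", "n_conditions_skewed",
                                       "conditions", "concordant",
                                       "mean_diff_log2", "direction"])
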