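"""ER-stress response: change in MPRA activity under thapsigargin (Tg)
versus DMSO solvent control, classified at FDR < 1%, plus row z-scores of
normalized RNA/DNA ratios for heatmap-style displays.

Both conditions come from the same library batch with the same number of
paired biological replicates, so the per-sequence contrast is a paired t
on the replicate-wise difference of log2 ratios (Tg - DMSO).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity import bh_adjust
from .skew import paired_t

__all__ = ["element_response", "test_response", "zscore_matrix"]


def test_response(ratios_dmso: pd.DataFrame, ratios_tg: pd.DataFrame,
                  fdr: float = 0.01) -> pd.DataFrame:
    """Classify each sequence as higher / lower / no_change under ER stress.

    ``ratios_dmso`` and ``ratios_tg`` are oligo × replicate log2-ratio
    matrices whose columns pair by position (replicate 1 with replicate 1,
    and so on).  Two-sided paired t per sequence on Tg - DMSO, BH across
    sequences, classes assigned by the sign of the mean difference at
    q < ``fdr``.
    """
    if ratios_dmso.shape[1] != ratios_tg.shape[1]:
        raise ValueError("DMSO and Tg must have the same number of paired replicates")
    if not ratios_dmso.index.equals(ratios_tg.index):
        raise ValueError("DMSO and Tg ratio matrices must cover the same oligos")
    diffs = ratios_tg.to_numpy() - ratios_dmso.to_numpy()
    stats_rows = [paired_t(d) for d in diffs]
    t = np.array([r[0] for r in stats_rows])
    p = np.array([r[1] for r in stats_rows])
    df = np.array([r[2] for r in stats_rows])
    mean_diff = diffs.mean(axis=1)
    q = bh_adjust(p)
    cls = np.where((q < fdr) & (mean_diff > 0), "higher",
                   np.where((q < fdr) & (mean_diff < 0), "lower", "no_change"))
    return pd.DataFrame({
        "oligo_id": ratios_dmso.index,
        "mean_diff_log2": mean_diff,
        "t": t,
        "df": df,
        "pvalue": p,
        "qvalue": q,
        "response": cls,
    }).reset_index(drop=True)


def element_response(response: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Element roll-up: higher if any allele is higher; lower if any allele
    is lower and none higher; otherwise no_change."""
    merged = response.merge(library[["oligo_id", "element_id"]], on="oligo_id", how="left")

    def roll(grp: pd.Series) -> str:
        if (grp == "higher").any():
            return "higher"
        if (grp == "lower").any():
            return "lower"
        return "no_change"

    out = merged.groupby("element_id")["response"].agg(roll).rename("response")
    return out.reset_index()


def zscore_matrix(ratios: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row z-scores of a ratio matrix: (x - row mean) / row sd, with the
    sample (n-1) standard deviation.

    Constant rows cannot be scaled; they are emitted as all-zero and flagged.
    Returns (z matrix, boolean Series of constant rows).
    """
    if ratios.shape[1] < 2:
        raise ValueError("z-scoring needs >=2 samples")
    x = ratios.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant] = 0.0
    zdf = pd.DataFrame(z, index=ratios.index, columns=ratios.columns)
    flags = pd.Series(constant, index=ratios.index, name="constant_row")
    return zdf, flags
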