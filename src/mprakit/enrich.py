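"""Annotation overlap and enrichment / concordance statistics.

Covers the statistical toolkit used to interpret MPRA calls against
external annotations: Fisher's exact tests on 2x2 tables (e.g. active
fraction by SNP category, repeat-class enrichment), Woolf log-method
odds-ratio confidence intervals, exact two-sided binomial tests of
direction concordance, the caQTL quadrant analysis, QQ comparison of eQTL
p-value groups, and per-locus Bonferroni adjustment of eQTL p-values for
genes within 1 Mb.

Coordinate conventions: BED-style intervals are 0-based half-open; SNP
positions in manifests are 1-based.  ``snp_to_interval`` is the single
conversion point.  Overlap means >=1 bp intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "binomial_concordance",
    "concordance_quadrants",
    "eqtl_qq",
    "fisher_2x2",
    "locus_eqtl_adjust",
    "odds_ratio_ci",
    "overlap_intervals",
    "snp_to_interval",
]

#: Repeat classes with enough tested elements to assess (all others pass
#: through unannotated).
REPEAT_CLASSES = ("LINE", "LTR", "SINE")


def snp_to_interval(pos_1based: int) -> tuple[int, int]:
    """Convert a 1-based SNP position to a 0-based half-open interval."""
    if pos_1based < 1:
        raise ValueError("1-based positions start at 1")
    return pos_1based - 1, pos_1based


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be nonnegative integers")
        m = np.array(self.as_array())
        if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
            raise ValueError("2x2 table has an all-zero margin")

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def _table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    arr = np.asarray(t)
    return ContingencyTable2x2(*(int(v) for v in arr.ravel()))


def fisher_2x2(table) -> dict:
    """Two-sided Fisher's exact test.

    p is the sum of hypergeometric probabilities of tables no more likely
    than the observed one.  The odds ratio is ad/bc, with a Haldane 0.5
    correction (flagged) when any cell is zero.
    """
    t = _table(table)
    p = float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])
    haldane = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = ((v + 0.5 for v in (t.a, t.b, t.c, t.d)) if haldane
                  else (t.a, t.b, t.c, t.d))
    return {"odds_ratio": (a * d) / (b * c), "pvalue": min(p, 1.0),
            "haldane": haldane}


def odds_ratio_ci(table, level: float = 0.95) -> dict:
    """Woolf log-method confidence interval for the odds ratio:
    exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)), Haldane-corrected
    (flagged) when any cell is zero."""
    t = _table(table)
    haldane = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = ((v + 0.5 for v in (t.a, t.b, t.c, t.d)) if haldane
                  else (t.a, t.b, t.c, t.d))
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return {"odds_ratio": float(np.exp(log_or)),
            "lower": float(np.exp(log_or - z * se)),
            "upper": float(np.exp(log_or + z * se)),
            "level": level, "haldane": haldane}


def binomial_concordance(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for k successes in n trials at null
    probability p0 (sum of outcome probabilities <= that of the observed
    outcome; no normal approximation)."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    return float(stats.binomtest(int(k), int(n), p0, alternative="two-sided").pvalue)


def concordance_quadrants(directions: pd.DataFrame) -> dict:
    """Quadrant tally for the MPRA-vs-external effect-direction scatter.

    ``directions`` has columns ``mpra`` and ``external`` holding signed
    effect values harmonized to the same (alternate) allele.  Rows where
    either direction is exactly zero are excluded and counted.  Quadrants:
    Q1 (+,+), Q2 (-,+ external/mpra axes: mpra<0, external>0), Q3 (-,-),
    Q4 (+,-); concordant fraction = (Q1+Q3)/total.
    """
    x = np.sign(directions["external"].to_numpy(dtype=float))
    y = np.sign(directions["mpra"].to_numpy(dtype=float))
    nonzero = (x != 0) & (y != 0)
    xs, ys = x[nonzero], y[nonzero]
    q1 = int(((xs > 0) & (ys > 0)).sum())
    q2 = int(((xs < 0) & (ys > 0)).sum())
    q3 = int(((xs < 0) & (ys < 0)).sum())
    q4 = int(((xs > 0) & (ys < 0)).sum())
    total = q1 + q2 + q3 + q4
    return {"Q1": q1, "Q2": q2, "Q3": q3, "Q4": q4,
            "n_zero_excluded": int((~nonzero).sum()),
            "concordant": q1 + q3,
            "total": total,
            "concordant_fraction": (q1 + q3) / total if total else float("nan")}


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------

def _build_trees(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, r in annotation.iterrows():
        start, end = int(r["start"]), int(r["end"])
        if start >= end:
            raise ValueError(f"malformed interval {r['chrom']}:{start}-{end}")
        trees.setdefault(r["chrom"], IntervalTree()).addi(start, end, r.get("label"))
    return trees


def overlap_intervals(elements: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Any-overlap (>=1 bp, half-open semantics) of each element against an
    annotation interval set.

    ``elements`` needs chrom/start/end (plus any id columns, preserved);
    ``annotation`` needs chrom/start/end and optionally ``label`` (e.g. the
    repeat class).  Returns the element rows with ``overlap`` (bool) and
    ``overlap_labels`` (comma-joined sorted labels of the hits).
    """
    trees = _build_trees(annotation)
    hits, labels = [], []
    for _, r in elements.iterrows():
        start, end = int(r["start"]), int(r["end"])
        if start >= end:
            raise ValueError(f"malformed interval {r['chrom']}:{start}-{end}")
        tree = trees.get(r["chrom"])
        found = sorted({iv.data for iv in tree.overlap(start, end)
                        if iv.data is not None}) if tree else []
        any_hit = bool(tree.overlap(start, end)) if tree else False
        hits.append(any_hit)
        labels.append(",".join(str(x) for x in found))
    out = elements.copy()
    out["overlap"] = hits
    out["overlap_labels"] = labels
    return out


# ---------------------------------------------------------------------------
# eQTL utilities
# ---------------------------------------------------------------------------

def eqtl_qq(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for a QQ plot.

    expected = -log10((rank - 0.5) / m) over ranks of the sorted p-values;
    observed = sorted -log10 p (descending).  p = 0 is clipped to the
    smallest positive float and flagged.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["expected", "observed", "clipped"])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    clipped = p == 0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    order = np.argsort(p)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p[order])
    return pd.DataFrame({"expected": expected, "observed": observed,
                         "clipped": clipped[order]})


def locus_eqtl_adjust(gene_pvals: pd.DataFrame, cutoff: float = 0.01) -> pd.DataFrame:
    """Bonferroni adjustment of nominal eQTL p-values for the m genes within
    1 Mb of a SNP: p_adj = min(1, m * p), significant iff p_adj < cutoff.

    ``gene_pvals`` has columns gene and pvalue (one locus per call); an
    empty table returns an empty result.
    """
    out = gene_pvals.copy()
    m = len(out)
    if m == 0:
        out["p_adjusted"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    if ((out["pvalue"] < 0) | (out["pvalue"] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out["p_adjusted"] = np.minimum(1.0, m * out["pvalue"].to_numpy(dtype=float))
    out["significant"] = out["p_adjusted"] < cutoff
    return out
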