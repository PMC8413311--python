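"""Sample sheet: which sequencing libraries are plasmid DNA vs RNA, and in
which culture condition and library batch they were made.

The experimental layout has two MPRA library batches: batch 1 is assayed
under standard culture, batch 2 under paired DMSO / thapsigargin (Tg)
treatments.  Plasmid-input samples belong to a batch but not a condition.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONDITIONS",
    "MATERIALS",
    "condition_batch",
    "default_sample_sheet",
    "validate_sample_sheet",
]

MATERIALS = ("plasmid", "rna")
CONDITIONS = ("standard", "dmso", "tg")

#: Condition → library batch. Standard culture used the first library prep;
#: the DMSO/Tg pair used the re-electroporated second prep, and the two preps
#: are never compared directly.
_CONDITION_BATCH = {"standard": 1, "dmso": 2, "tg": 2}

COLUMNS = ["sample_id", "material", "condition", "replicate", "batch"]


def condition_batch(condition: str) -> int:
    """Library batch in which a culture condition was assayed."""
    try:
        return _CONDITION_BATCH[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def default_sample_sheet(n_rna: int = 5, n_dna: int = 1,
                         conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Reference layout: ``n_dna`` plasmid samples per batch and ``n_rna``
    RNA replicates per condition (the study design used 5 RNA replicates)."""
    rows = []
    batches = sorted({condition_batch(c) for c in conditions})
    for b in batches:
        for r in range(1, n_dna + 1):
            rows.append((f"dna_b{b}_r{r}", "plasmid", None, r, b))
    for c in conditions:
        for r in range(1, n_rna + 1):
            rows.append((f"rna_{c}_r{r}", "rna", c, r, condition_batch(c)))
    return pd.DataFrame(rows, columns=COLUMNS)


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns the sheet unchanged.

    Raises ``ValueError`` if a batch lacks a plasmid sample, a condition has
    fewer than 2 RNA replicates, or a condition sits in the wrong batch.
    """
    missing = set(COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = samples.loc[~samples["material"].isin(MATERIALS), "material"]
    if len(bad):
        raise ValueError(f"unknown material values: {sorted(set(bad))}")
    rna = samples[samples["material"] == "rna"]
    bad = rna.loc[~rna["condition"].isin(CONDITIONS), "condition"]
    if len(bad):
        raise ValueError(f"unknown conditions: {sorted(set(bad))}")
    for cond, grp in rna.groupby("condition"):
        if len(grp) < 2:
            raise ValueError(f"condition {cond!r} has {len(grp)} RNA replicates; need >=2")
        wrong = grp[grp["batch"] != condition_batch(cond)]
        if len(wrong):
            raise ValueError(f"condition {cond!r} samples assigned to wrong batch")
    for b in samples["batch"].unique():
        dna = samples[(samples["batch"] == b) & (samples["material"] == "plasmid")]
        if len(dna) < 1:
            raise ValueError(f"batch {b} has no plasmid sample")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id")
    return samples


def rna_samples(samples: pd.DataFrame, condition: str) -> list[str]:
    sel = (samples["material"] == "rna") & (samples["condition"] == condition)
    return list(samples.loc[sel, "sample_id"])


def dna_samples(samples: pd.DataFrame, batch: int) -> list[str]:
    sel = (samples["material"] == "plasmid") & (samples["batch"] == batch)
    return list(samples.loc[sel, "sample_id"])
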