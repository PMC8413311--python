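"""File formats and pipeline configuration.

Strict readers for the plain-text formats the pipeline exchanges: BED
(0-based half-open, class label in column 4), FASTQ (via Biopython,
gzip-aware), and TSV count tables (nonnegative integers only; malformed
rows are rejected with their line number).  Writers round-trip losslessly
through these readers.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PipelineConfig",
    "read_bed",
    "read_config",
    "read_fastq",
    "read_tsv_counts",
    "write_config",
    "write_tsv",
]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into chrom/start/end(/label) with validation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            label = parts[3] if len(parts) > 3 else None
            rows.append((parts[0], start, end, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def read_fastq(path):
    """Iterate (read_id, sequence, quality) records; gzip-aware."""
    from Bio import SeqIO
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def read_tsv_counts(path, index_col: str | None = None) -> pd.DataFrame:
    """Read a count table (rows = barcodes or oligos, columns = samples);
    every entry must be a nonnegative integer."""
    df = pd.read_csv(path, sep="\t", index_col=0 if index_col is None else index_col)
    numeric = df.select_dtypes(exclude="number")
    if len(numeric.columns):
        raise ValueError(f"{path}: non-numeric count columns {list(numeric.columns)}")
    bad = (df < 0) | (df != df.round())
    if bad.any().any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: negative or non-integer count at line {row + 2}")
    return df.astype("int64")


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> str:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return str(path)


@dataclass
class PipelineConfig:
    """All thresholds and simulation settings, serializable to YAML.

    The fixed analysis constants: activity FDR 1%, skew FDR 10%, response
    FDR 1%, LD membership r^2 >= 0.8, per-locus Bonferroni cutoff 0.01.
    """

    # analysis thresholds
    fdr_activity: float = 0.01
    fdr_skew: float = 0.10
    fdr_response: float = 0.01
    r2_min: float = 0.8
    bonferroni_locus: float = 0.01
    pseudocount: float = 1.0
    dispersion_shrink: float = 0.5
    one_sided_activity: bool = False
    fdr_method: str = "fdr_bh"
    barcode_offset: int = 0
    # simulation settings
    seed: int = 0
    n_elements: int = 400
    category_props: tuple[float, float, float] = (0.38, 0.29, 0.33)
    n_signals: int = 30
    frac_two_snp: float = 0.05
    barcodes_per_oligo: int = 30
    ambiguous_rate: float = 0.02
    depth: float = 1_000_000
    dna_dispersion: float = 0.01
    n_rna_replicates: int = 5
    n_dna_replicates: int = 1
    frac_active: float = 0.30
    activity_log2fc: float = 1.5
    frac_skew: float = 0.44
    allelic_effect_log2: float = 1.0
    frac_higher: float = 0.025
    frac_lower: float = 0.05
    condition_log2fc: float = 1.5
    alpha_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self):
        for name in ("fdr_activity", "fdr_skew", "fdr_response",
                     "r2_min", "bonferroni_locus"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_props"] = list(d["category_props"])
        d["alpha_range"] = list(d["alpha_range"])
        return d


def write_config(config: PipelineConfig, path) -> str:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return str(path)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("category_props", "alpha_range"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def write_json(obj, path) -> str:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
    return str(path)
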