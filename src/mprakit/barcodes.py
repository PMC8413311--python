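"""Barcode→oligo dictionary construction, read counting, and aggregation.

Barcodes pairing with more than one oligo are discarded from all downstream
analyses; counting is exact-match only (no mismatch rescue — in a random
20-mer space, one-off collisions are negligible at library scale).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .simulate import BARCODE_LEN

__all__ = [
    "BarcodeAssignment",
    "BarcodeCounts",
    "aggregate_counts",
    "build_barcode_map",
    "count_barcodes",
]

_BARCODE_RE = re.compile(r"^[ACGT]{20}$")


@dataclass
class BarcodeAssignment:
    """Usable barcode→oligo dictionary plus the discarded ambiguous set."""

    usable: dict[str, str]
    ambiguous: dict[str, tuple[str, ...]]
    n_malformed: int = 0

    @property
    def oligo_ids(self) -> list[str]:
        return sorted(set(self.usable.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(bc, oid, False, oid) for bc, oid in self.usable.items()]
        rows += [(bc, oids[0], True, ",".join(oids)) for bc, oids in self.ambiguous.items()]
        return pd.DataFrame(rows, columns=["barcode", "oligo_id", "ambiguous", "oligo_ids"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BarcodeAssignment":
        usable, ambiguous = {}, {}
        for _, r in df.iterrows():
            if bool(r["ambiguous"]):
                ambiguous[r["barcode"]] = tuple(str(r["oligo_ids"]).split(","))
            else:
                usable[r["barcode"]] = r["oligo_id"]
        return cls(usable=usable, ambiguous=ambiguous)


def build_barcode_map(pairings: Iterable[tuple[str, str]]) -> BarcodeAssignment:
    """Collapse (barcode, oligo_id) pairings into a usable dictionary.

    Barcodes observed with ≥2 distinct oligos are marked ambiguous and
    excluded from the usable map.  Duplicate identical pairings collapse.
    Malformed barcodes (not 20-mers over ACGT) are skipped and counted.
    """
    seen: dict[str, set[str]] = {}
    n_malformed = 0
    for barcode, oligo_id in pairings:
        if not isinstance(barcode, str) or not _BARCODE_RE.match(barcode):
            n_malformed += 1
            continue
        seen.setdefault(barcode, set()).add(oligo_id)
    usable = {bc: next(iter(oids)) for bc, oids in seen.items() if len(oids) == 1}
    ambiguous = {bc: tuple(sorted(oids)) for bc, oids in seen.items() if len(oids) > 1}
    return BarcodeAssignment(usable=usable, ambiguous=ambiguous, n_malformed=n_malformed)


@dataclass
class BarcodeCounts:
    """Per-sample barcode tallies and read-fate counters.

    Invariant: matched + unmatched + ambiguous_discarded +
    n_containing_discarded = total_reads.  Reads shorter than the barcode
    window are tallied under ``unmatched`` (and separately as ``truncated``).
    """

    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    matched: int = 0
    unmatched: int = 0
    ambiguous_discarded: int = 0
    n_containing_discarded: int = 0
    truncated: int = 0

    def summary(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "matched": self.matched,
            "unmatched": self.unmatched,
            "ambiguous_discarded": self.ambiguous_discarded,
            "n_containing_discarded": self.n_containing_discarded,
            "truncated": self.truncated,
        }


def _iter_fastq_seqs(reads) -> Iterator[str]:
    """Yield sequences from a FASTQ path (plain or .gz) or an iterable of
    sequence strings (for in-memory use)."""
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        yield from reads


def count_barcodes(reads, assignment: BarcodeAssignment, offset: int = 0) -> BarcodeCounts:
    """Tally exact barcode matches at a fixed read offset.

    Reads whose barcode window contains N are discarded and counted; reads
    matching an ambiguous barcode are counted under ``ambiguous_discarded``;
    everything else that is not in the usable map is ``unmatched``.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    bc = BarcodeCounts()
    usable = assignment.usable
    ambiguous = assignment.ambiguous
    end = offset + BARCODE_LEN
    for seq in _iter_fastq_seqs(reads):
        bc.total_reads += 1
        if len(seq) < end:
            bc.truncated += 1
            bc.unmatched += 1
            continue
        window = seq[offset:end].upper()
        if "N" in window:
            bc.n_containing_discarded += 1
            continue
        if window in usable:
            bc.matched += 1
            bc.counts[window] = bc.counts.get(window, 0) + 1
        elif window in ambiguous:
            bc.ambiguous_discarded += 1
        else:
            bc.unmatched += 1
    return bc


def aggregate_counts(barcode_counts, assignment: BarcodeAssignment,
                     oligo_ids: list[str] | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Sum barcode counts to per-oligo counts.

    ``barcode_counts`` is either a barcode × sample DataFrame (ambiguous
    barcodes allowed; they are dropped) or a {sample: BarcodeCounts} mapping.
    Barcodes neither usable nor ambiguous raise a consistency error.  Oligos
    with no surviving barcodes are emitted as zero rows.

    Returns (oligo × sample integer DataFrame, per-oligo n_barcodes_observed).
    """
    if isinstance(barcode_counts, dict):
        frames = {s: pd.Series(c.counts, dtype=np.int64) for s, c in barcode_counts.items()}
        mat = pd.DataFrame(frames).fillna(0).astype(np.int64)
        mat.index.name = "barcode"
    else:
        mat = barcode_counts
    unknown = [b for b in mat.index if b not in assignment.usable and b not in assignment.ambiguous]
    if unknown:
        raise ValueError(f"{len(unknown)} counted barcodes absent from the barcode map "
                         f"(e.g. {unknown[0]!r})")
    keep = [b for b in mat.index if b in assignment.usable]
    sub = mat.loc[keep]
    owners = pd.Index([assignment.usable[b] for b in keep], name="oligo_id")
    grouped = sub.groupby(owners).sum()
    n_bc = sub.groupby(owners).apply(lambda d: int((d.sum(axis=1) > 0).sum()), include_groups=False)
    universe = oligo_ids if oligo_ids is not None else assignment.oligo_ids
    grouped = grouped.reindex(universe, fill_value=0).astype(np.int64)
    n_bc = n_bc.reindex(universe, fill_value=0).astype(np.int64)
    n_bc.name = "n_barcodes_observed"
    grouped.index.name = "oligo_id"
    return grouped, n_bc
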