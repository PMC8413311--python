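"""Synthetic MPRA experiments with known truth.

Generates an oligo library (200 bp elements carrying SNP alleles in three
design categories), a barcode→oligo pairing with a controllable ambiguity
rate, and barcode-level sequencing counts drawn from the same negative-
binomial model family the analysis fits:

    count ~ NB(mean = depth * softmax(abundance * weight * 2^{β·RNA} * 2^{τ·Tg}),
               dispersion α_oligo)

where β is the per-oligo transcriptional activity (log2 RNA vs plasmid),
τ a per-element ER-stress multiplier applied in thapsigargin-treated RNA
samples, and the per-barcode lognormal weight models cloning/PCR
representation variability.  Plasmid (DNA) samples carry no activity effect.
Two library batches have independent plasmid abundance draws, mirroring the
two separate library preparations (standard culture vs DMSO/Tg).

Everything is deterministic given the root seed: each stage draws from a
child stream keyed by a fixed label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .samples import condition_batch, validate_sample_sheet

__all__ = [
    "CATEGORIES",
    "LIBRARY_COLUMNS",
    "TruthTable",
    "filter_non_caqtl_candidates",
    "simulate_barcode_map",
    "simulate_counts",
    "simulate_library",
    "simulate_truth",
    "write_reads",
]

CATEGORIES = ("T2D", "caQTL", "nonCaQTL")

LIBRARY_COLUMNS = [
    "oligo_id", "element_id", "snp_ids", "allele_combo", "chrom",
    "snp_pos", "start", "end", "category", "signal_id", "is_indel",
]

ELEMENT_LEN = 200
BARCODE_LEN = 20
_BASES = np.array(list("ACGT"))


def simulate_library(n_elements: int,
                     category_props: tuple[float, float, float] = (0.38, 0.29, 0.33),
                     n_signals: int = 10,
                     frac_two_snp: float = 0.05,
                     frac_indel: float = 0.08,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate an oligo library manifest.

    Each element is a 200 bp window centred on a SNP; its oligos carry all
    allele combinations (2 for one SNP, 4 for two SNPs <25 bp apart, as in
    the paired-caQTL design).  Categories (T2D / caQTL / nonCaQTL) are drawn
    multinomially with ``category_props``; every T2D element is assigned to
    one of ``n_signals`` GWAS association signals.  Deterministic given
    ``seed``.
    """
    if n_elements < 0:
        raise ValueError("n_elements must be >= 0")
    props = np.asarray(category_props, dtype=float)
    if props.shape != (3,) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("category_props must be 3 nonnegative numbers summing to 1")
    rng = child_rng(seed, "library")
    rows: list[tuple] = []
    snp_counter = 0
    has_t2d = False
    cats = rng.choice(len(CATEGORIES), size=n_elements, p=props)
    two_snp = rng.random(n_elements) < frac_two_snp
    chroms = rng.integers(1, 23, size=n_elements)
    positions = rng.integers(10_000_000, 200_000_000, size=n_elements)
    signal_ids = rng.integers(0, max(n_signals, 1), size=n_elements)
    indels = rng.random(n_elements) < frac_indel
    for e in range(n_elements):
        category = CATEGORIES[cats[e]]
        element_id = f"el{e:05d}"
        chrom = f"chr{chroms[e]}"
        pos = int(positions[e])  # 1-based position of the (first) SNP
        n_snp = 2 if two_snp[e] else 1
        snps = [f"snp{snp_counter + k:06d}" for k in range(n_snp)]
        snp_counter += n_snp
        if category == "T2D":
            if n_signals < 1:
                raise ValueError("n_signals must be >= 1 when T2D elements are simulated")
            signal = f"sig{signal_ids[e]:04d}"
            has_t2d = True
        else:
            signal = None
        is_indel = bool(indels[e]) and category == "T2D"
        start = pos - 101  # 0-based half-open window; SNP at offset 100
        end = start + ELEMENT_LEN
        combos = ["R", "A"] if n_snp == 1 else ["RR", "RA", "AR", "AA"]
        for combo in combos:
            rows.append((f"{element_id}_{combo}", element_id, ",".join(snps), combo,
                         chrom, pos, start, end, category, signal, is_indel))
    lib = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    if has_t2d and n_signals < 1:  # pragma: no cover - guarded above
        raise ValueError("n_signals must be >= 1")
    return lib


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    missing = set(LIBRARY_COLUMNS) - set(library.columns)
    if missing:
        raise ValueError(f"library manifest missing columns: {sorted(missing)}")
    if library["oligo_id"].duplicated().any():
        raise ValueError("duplicate oligo_id in library")
    if len(library):
        sizes = library.groupby("element_id").size()
        if (~sizes.isin([2, 4])).any():
            raise ValueError("each element must have 2 (one SNP) or 4 (two SNPs) oligos")
        if ((library["end"] - library["start"]) != ELEMENT_LEN).any():
            raise ValueError(f"element intervals must have length {ELEMENT_LEN}")
    return library


def filter_non_caqtl_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Apply the non-caQTL inclusion filters to a candidate SNP table.

    Retains SNPs for which the chromatin-accessibility association study was
    well powered yet found nothing: unadjusted caQTL p > 0.2 AND minor allele
    frequency > 0.125 (both strict), excluding SNPs in individual-specific
    peaks or sharing a peak with another SNP.  Row order is preserved.
    """
    required = {"snp_id", "caqtl_p_unadjusted", "maf",
                "individual_specific_peak", "peak_shared"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    keep = (
        (candidates["caqtl_p_unadjusted"] > 0.2)
        & (candidates["maf"] > 0.125)
        & ~candidates["individual_specific_peak"].astype(bool)
        & ~candidates["peak_shared"].astype(bool)
    )
    return candidates.loc[keep].copy()


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth behind a simulated experiment.

    oligos:   per-oligo generative parameters (batch abundances, activity
              β in log2, Tg multiplier τ in log2, NB dispersion α).
    snps:     per-SNP truth (allelic effect in log2, skew flag, direction).
    elements: per-element truth (active flag, ER-stress response class).
    """

    oligos: pd.DataFrame
    snps: pd.DataFrame
    elements: pd.DataFrame


def simulate_truth(library: pd.DataFrame,
                   frac_active: float = 0.30,
                   activity_log2fc: float = 1.5,
                   frac_skew: float = 0.44,
                   allelic_effect_log2: float = 1.0,
                   frac_higher: float = 0.025,
                   frac_lower: float = 0.05,
                   condition_log2fc: float = 1.5,
                   alpha_range: tuple[float, float] = (0.05, 0.5),
                   abundance_sigma: float = 0.5,
                   skew_snps: list[str] | None = None,
                   seed: int = 0) -> TruthTable:
    """Draw a truth table over a library.

    ``frac_active`` of elements get activity β = ``activity_log2fc`` (log2,
    RNA over plasmid); among active elements, ``frac_skew`` of SNPs get an
    allelic effect of ±``allelic_effect_log2`` (random sign) added to their
    alternate-allele oligos.  ``frac_higher``/``frac_lower`` of elements gain
    a ±``condition_log2fc`` multiplier in Tg-treated RNA.  Dispersions are
    uniform on ``alpha_range``; per-batch log abundances are Normal(0, σ).

    ``skew_snps`` overrides the random skew draw with an explicit SNP set
    (their elements are forced active so the effect is observable, matching
    the analysis convention that skew is only assessed on active sequences).
    """
    rng = child_rng(seed, "truth")
    lib = library.reset_index(drop=True)
    elements = lib["element_id"].unique()
    n_el = len(elements)

    active_draw = rng.random(n_el) < frac_active
    resp_draw = rng.random(n_el)
    resp_class = np.where(resp_draw < frac_higher, "higher",
                          np.where(resp_draw < frac_higher + frac_lower, "lower", "no_change"))
    el_truth = pd.DataFrame({
        "element_id": elements,
        "true_active": active_draw,
        "true_response": resp_class,
    })

    # SNP truth: skew only among active elements unless explicitly listed
    snp_rows = []
    el_active = dict(zip(el_truth["element_id"], el_truth["true_active"]))
    seen: set[str] = set()
    for _, row in lib.drop_duplicates("element_id").iterrows():
        for snp in row["snp_ids"].split(","):
            if snp in seen:
                continue
            seen.add(snp)
            snp_rows.append((snp, row["element_id"]))
    snp_df = pd.DataFrame(snp_rows, columns=["snp_id", "element_id"])
    if skew_snps is not None:
        is_skew = snp_df["snp_id"].isin(set(skew_snps)).to_numpy()
        for el in snp_df.loc[is_skew, "element_id"]:
            el_active[el] = True
        el_truth["true_active"] = el_truth["element_id"].map(el_active)
    else:
        eligible = snp_df["element_id"].map(el_active).to_numpy(dtype=bool)
        is_skew = eligible & (rng.random(len(snp_df)) < frac_skew)
    signs = rng.choice([-1.0, 1.0], size=len(snp_df))
    effect = np.where(is_skew, signs * allelic_effect_log2, 0.0)
    snp_df["allelic_effect_log2"] = effect
    snp_df["true_skew"] = is_skew
    snp_df["true_direction"] = np.where(~is_skew, "none",
                                        np.where(effect > 0, "alt_up", "ref_up"))

    # Per-oligo parameters
    n = len(lib)
    el_map = el_truth.set_index("element_id")
    snp_eff = dict(zip(snp_df["snp_id"], snp_df["allelic_effect_log2"]))
    beta = np.zeros(n)
    tau = np.zeros(n)
    for i, row in lib.iterrows():
        el = row["element_id"]
        b = activity_log2fc if el_map.at[el, "true_active"] else 0.0
        for snp, allele in zip(row["snp_ids"].split(","), row["allele_combo"]):
            if allele == "A":
                b += snp_eff[snp]
        beta[i] = b
        cls = el_map.at[el, "true_response"]
        tau[i] = condition_log2fc if cls == "higher" else (-condition_log2fc if cls == "lower" else 0.0)
    lo, hi = alpha_range
    if lo <= 0:
        raise ValueError("dispersion must be positive")
    oligo_truth = pd.DataFrame({
        "oligo_id": lib["oligo_id"],
        "element_id": lib["element_id"],
        "log_abundance_b1": rng.normal(0.0, abundance_sigma, size=n),
        "log_abundance_b2": rng.normal(0.0, abundance_sigma, size=n),
        "activity_log2fc": beta,
        "condition_log2fc": tau,
        "dispersion": rng.uniform(lo, hi, size=n),
    })
    return TruthTable(oligos=oligo_truth, snps=snp_df, elements=el_truth)


# ---------------------------------------------------------------------------
# Barcode map
# ---------------------------------------------------------------------------

def _random_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    if n > 4 ** BARCODE_LEN // 2:  # pragma: no cover - astronomically large
        raise ValueError("barcode space exhausted")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), BARCODE_LEN))
        for row in draw:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_barcode_map(library: pd.DataFrame,
                         barcodes_per_oligo: int | tuple[str, float] = 30,
                         ambiguous_rate: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate the barcode→oligo pairing table.

    ``barcodes_per_oligo`` is either a fixed integer or ``("poisson", mean)``
    (shifted so every oligo keeps ≥1 barcode).  Each barcode is independently
    ambiguous with probability ``ambiguous_rate``, in which case it is also
    paired with a second, random oligo — such barcodes are discarded by the
    analysis but still generate reads.

    Returns a DataFrame with columns barcode, oligo_id (primary assignment),
    ambiguous (bool), oligo_ids (comma-joined full assignment set).
    """
    if not 0 <= ambiguous_rate < 1:
        raise ValueError("ambiguous_rate must be in [0, 1)")
    rng = child_rng(seed, "barcode_map")
    oligos = list(library["oligo_id"])
    if not oligos:
        return pd.DataFrame(columns=["barcode", "oligo_id", "ambiguous", "oligo_ids"])
    if isinstance(barcodes_per_oligo, tuple):
        kind, mean = barcodes_per_oligo
        if kind != "poisson":
            raise ValueError(f"unknown barcode count distribution {kind!r}")
        per = 1 + rng.poisson(max(mean - 1, 0), size=len(oligos))
    else:
        if barcodes_per_oligo < 1:
            raise ValueError("barcodes_per_oligo must be >= 1")
        per = np.full(len(oligos), int(barcodes_per_oligo))
    total = int(per.sum())
    barcodes = _random_barcodes(total, rng)
    owner = np.repeat(np.arange(len(oligos)), per)
    ambiguous = rng.random(total) < ambiguous_rate
    rows = []
    for k in range(total):
        primary = oligos[owner[k]]
        if ambiguous[k] and len(oligos) > 1:
            other = oligos[(owner[k] + 1 + rng.integers(0, len(oligos) - 1)) % len(oligos)]
            rows.append((barcodes[k], primary, True, f"{primary},{other}"))
        else:
            rows.append((barcodes[k], primary, False, primary))
    return pd.DataFrame(rows, columns=["barcode", "oligo_id", "ambiguous", "oligo_ids"])


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(library: pd.DataFrame,
                    barcode_map: pd.DataFrame,
                    truth: TruthTable,
                    samples: pd.DataFrame,
                    depth: float = 1_000_000,
                    barcode_sigma: float = 0.5,
                    dna_dispersion: float = 0.01,
                    seed: int = 0) -> pd.DataFrame:
    """Draw barcode-level NB counts for every sample in the sheet.

    Returns a barcode × sample integer DataFrame (index = barcode).  RNA
    samples carry the activity effect 2^β and, in Tg, the condition
    multiplier 2^τ; plasmid samples carry neither.  The two batches use
    independent abundance draws and independent barcode weights.

    RNA replicates use the per-oligo biological dispersion α_i from the
    truth table (transfection-to-transfection variability).  Plasmid
    samples re-measure one physical pool, so they carry only the small
    technical overdispersion ``dna_dispersion``.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    validate_sample_sheet(samples)
    ot = truth.oligos.set_index("oligo_id")
    oligo_ix = barcode_map["oligo_id"].to_numpy()
    n_bc = len(barcode_map)
    log_ab = {1: ot["log_abundance_b1"], 2: ot["log_abundance_b2"]}
    beta = ot["activity_log2fc"]
    tau = ot["condition_log2fc"]
    alpha = ot.loc[oligo_ix, "dispersion"].to_numpy() if n_bc else np.array([])

    weights = {}
    for b in (1, 2):
        wrng = child_rng(seed, "weights", b)
        weights[b] = np.exp(wrng.normal(0.0, barcode_sigma, size=n_bc))

    out = {}
    ln2 = np.log(2.0)
    for _, s in samples.iterrows():
        rng = child_rng(seed, "counts", s["sample_id"])
        if n_bc == 0:
            out[s["sample_id"]] = np.zeros(0, dtype=np.int64)
            continue
        rate = np.exp(log_ab[s["batch"]].loc[oligo_ix].to_numpy()) * weights[s["batch"]]
        if s["material"] == "rna":
            rate = rate * np.exp(ln2 * beta.loc[oligo_ix].to_numpy())
            if s["condition"] == "tg":
                rate = rate * np.exp(ln2 * tau.loc[oligo_ix].to_numpy())
            a = alpha
        else:
            a = np.full(n_bc, float(dna_dispersion))
        mu = depth * rate / rate.sum()
        lam = np.where(a > 1e-8,
                       rng.gamma(1.0 / np.maximum(a, 1e-8), np.maximum(a, 1e-8) * mu),
                       mu)
        out[s["sample_id"]] = rng.poisson(lam).astype(np.int64)
    return pd.DataFrame(out, index=pd.Index(barcode_map["barcode"], name="barcode"))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

#: Constant vector sequence flanking the barcode in the 31 bp barcode read.
_FLANK = "TCTAGAGGTACCGGTAGGCATCAACGTCTAG"


def write_reads(counts: pd.DataFrame, out_dir, offset: int = 0,
                read_length: int = 31, seed: int = 0) -> dict[str, str]:
    """Write one FASTQ per sample; each barcode appears exactly its count.

    The barcode occupies ``[offset, offset+20)`` of every read; the rest is a
    constant vector flank.  Read order is shuffled per sample (seeded).
    Returns {sample_id: path}.
    """
    from pathlib import Path
    if offset < 0 or offset + BARCODE_LEN > read_length:
        raise ValueError("layout inconsistent: need offset + 20 <= read_length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qual = "I" * read_length
    prefix = _FLANK[:offset]
    suffix_len = read_length - offset - BARCODE_LEN
    suffix = (_FLANK * (suffix_len // len(_FLANK) + 1))[:suffix_len]
    paths = {}
    barcodes = np.asarray(counts.index)
    for sample in counts.columns:
        rng = child_rng(seed, "reads", sample)
        cvec = counts[sample].to_numpy()
        order = np.repeat(np.arange(len(barcodes)), cvec)
        rng.shuffle(order)
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, bi in enumerate(order):
                fh.write(f"@{sample}:{i}\n{prefix}{barcodes[bi]}{suffix}\n+\n{qual}\n")
        paths[sample] = str(path)
    return paths
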