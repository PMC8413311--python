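# Methods

## The assay and the analysis model

A massively parallel reporter assay (MPRA) clones thousands of 200 bp
candidate regulatory sequences upstream of a minimal promoter driving a
reporter transcript whose 3′UTR carries a 20 nt barcode unique to each
oligo. Transcriptional activity is read out as the abundance of each
barcode in mRNA relative to the input plasmid pool. The designs handled
here carry both alleles of each SNP (and all four combinations for pairs of
SNPs under 25 bp apart), in three categories: T2D-GWAS-associated SNPs
grouped into LD signals (r² ≥ 0.8 with an index SNP), islet chromatin
accessibility QTLs (caQTLs), and non-caQTL SNPs that sit in accessible
chromatin but passed well-powered negative filters (unadjusted caQTL
p > 0.2 and MAF > 0.125, excluding individual-specific or shared peaks).

The analysis chain is:

1. **Barcode counting.** Exact-match lookup of the 20-mer at a fixed read
   offset. Barcodes pairing with more than one oligo are discarded
   everywhere; reads with N in the barcode window are dropped and counted.
   Per-oligo counts are the sums of their surviving barcodes.
2. **Normalization.** Median-of-ratios size factors
   s_j = median_i (K_ij / geomean_i), computed within a library batch
   across that batch's plasmid and RNA samples jointly, over the oligos
   with all-positive counts. The median is taken in linear space.
3. **Activity.** Per oligo, counts follow NB(μ_ij, α_i) with
   μ_ij = s_j · q_i · 2^{β_i·1[RNA_j]}; β_i is the log2 fold change of RNA
   over plasmid. Because the RNA indicator splits samples into two groups,
   the MLE separates into two one-parameter group-mean problems solved by
   damped Newton iterations vectorized across oligos. The Wald statistic
   uses the observed Fisher information, which is diagonal in the
   (log m_DNA, log m_RNA) parametrization. A sequence is "MPRA active"
   when its Benjamini–Hochberg q-value is below 1% **and** β̂ > 0
   (activation; depletion is reported but not called active).
4. **Allelic skew.** For contrasts where at least one allele's sequence is
   active in that condition, a two-sided paired t-test on the
   replicate-wise difference of log2 ratios
   ρ_ir = log2((K_ir/s_r + c)/(D_i + c)) between alleles, BH within
   condition, skew at q < 10%. D_i is the batch plasmid profile (mean of
   normalized plasmid counts); size factors are re-anchored to the plasmid
   profile so the pseudocount c (default 1) is in plasmid-scale units and
   rescaling any single RNA replicate is absorbed exactly. Two-SNP
   elements contribute one contrast per SNP per fixed background allele of
   the partner SNP; a SNP shows skew if any of its contrasts does.
5. **ER-stress response.** Paired t on Δρ (Tg − DMSO, paired by
   replicate), BH across sequences, classes {higher, lower, no_change} at
   q < 1% by the sign of the mean difference. An element is "higher" if
   any allele is higher, "lower" if any is lower and none higher.
6. **Enrichment statistics.** Exact two-sided Fisher tests (minimum-
   likelihood definition) with Haldane-corrected odds ratios on zero
   cells; Woolf log-method CIs; exact two-sided binomial concordance
   tests; quadrant tallies of sign agreement; QQ quantile pairs with
   expected = −log10((rank − 0.5)/m); per-locus Bonferroni adjustment
   p_adj = min(1, m·p) at cutoff 0.01 for the m genes within 1 Mb.
7. **Nomination.** Skew calls are rolled up to GWAS signals (members at
   r² ≥ 0.8 with the index SNP). A member is a candidate if skewed in ≥1
   condition; signals are classified none / single_candidate /
   two_candidates / multi_candidate by candidate count. Overlapping LD
   blocks stay distinct; a shared SNP contributes to each.

### Batch firewall

Standard-culture RNA is compared only against the batch-1 plasmid input,
and DMSO/Tg only against batch-2: the two library preparations are
physically different pools and are never compared to each other. Condition
merging happens only at the level of per-SNP calls (union + direction
concordance), never at the level of counts.

### Dispersion recipe

The NB dispersion α_i (variance μ + αμ²) is estimated per oligo by a
profile MLE over a refined log-α grid (the two group means are re-solved
at each candidate α), then shrunk toward a rolling-median trend of log α
over the 50 oligos of nearest base mean:
log α_final = (1−λ)·log α̂ + λ·log α_trend with λ = 0.5 and a floor of
1e-8. The contract of this recipe is calibration of the null (the fully
null false-call rate), not bit-parity with any particular package; the
single-oligo `fit_nb` path additionally polishes α̂ with a bounded scalar
maximization so it agrees with a 2-D grid-search MLE oracle.

### Degenerate inputs and numerical conventions

All-zero oligos and oligos with zero plasmid counts in every DNA sample
are flagged untested, never silently given NA p-values. An all-zero count
group in a tested oligo receives a half-count continuity correction, which
keeps the contrast finite with a conservatively large SE. Paired
differences that are identically zero give p = 1; identical nonzero
differences are treated as having machine-epsilon spread (p ≈ 0, flagged
degenerate). p = 0 inputs to QQ construction are clipped to the smallest
positive float and flagged. Binomial and hypergeometric tails come from
scipy's exact routines (log-space, never a normal approximation). BED
intervals are 0-based half-open; SNP manifest positions are 1-based;
`snp_to_interval` is the single conversion point. Overlap means ≥1 bp
intersection. Only LINE, LTR and SINE repeat classes are assessed; other
classes pass through unannotated.

## The synthetic-data generator

The generator mirrors the analysis model so every stage is testable with
known truth. Barcode-level counts are NB with mean
depth · softmax(exp(a_i^{(batch)}) · w_k · 2^{β_i·1[RNA]} · 2^{τ_i·1[Tg]}),
where a_i is a per-oligo, per-batch log abundance (Normal(0, 0.5)), w_k a
per-barcode lognormal weight (σ = 0.5) modeling cloning/PCR
representation, β_i the planted activity (+ allelic effect on
alternate-allele oligos), and τ_i a per-element Tg multiplier. The two
batches draw abundances and weights independently, mirroring the two
library preparations. Indels are metadata only; no sequence realization.

RNA replicates use the per-oligo biological dispersion α_i (default
uniform on [0.05, 0.5]); plasmid samples re-measure one physical pool and
carry only a small technical dispersion (default 0.01). This distinction
matters: the paired-ratio skew test shares a single plasmid denominator
across all RNA replicates, so plasmid measurement error acts as a fixed
per-contrast offset that no amount of replicate averaging removes. The
test is therefore only calibrated when the plasmid profile is measured
much more precisely than any single RNA replicate — which is exactly how
the assay is run (one deeply sequenced input pool). For the same reason
the reference recovery and end-to-end configurations use five technical
plasmid replicates; the simulator's default remains one plasmid sample
per batch.

Because barcode counts are renormalized to a fixed depth (softmax),
activity is relative to the pool: if every element were boosted equally,
nothing would look active. Planted effects are therefore recovered
slightly damped when a large fraction of the library is active, and the
generator's defaults keep the active fraction near 30%, matching the
regime the assay operates in.

What the generator does **not** emulate: sequencing errors and quality
variation, GC/mappability bias, barcode collisions by mutation,
transfection-batch correlations between oligos (each oligo's replicates
are independent), and real LD structure (signals are labels, r² values are
drawn uniformly on [0.8, 1]). Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the assay's
own model assumptions, not robustness to every artifact of real data.

## Reference study conditions

* **Null calibration** — 2,000 oligos, one barcode per oligo (so α_i is
  the oligo-level dispersion), 1 plasmid + 5 RNA replicates per condition,
  α ~ U[0.05, 0.5], mean depth 200 reads/oligo, no planted effects,
  10 seeds. Reported: fraction of q<1% active calls among tested oligos,
  and falsely-reported skew contrasts per library contrast. The latter
  denominator is all contrasts the library defines: on a null library
  almost no contrast becomes eligible for testing (eligibility requires an
  active sequence), so the eligible-only fraction would be a ratio of two
  near-zero counts.
* **Parameter recovery** — 250 elements, 30 barcodes/oligo, planted
  β = 1.5 log2 on half the elements and Δ = ±1 log2 on half of their SNPs,
  5 RNA + 5 technical plasmid replicates, nominal depth 250 reads/oligo
  (realized median base mean ≈ 200 after softmax damping). Reported:
  activity/skew sensitivity, skew direction accuracy, empirical skew FDR.
* **End-to-end nomination** — 300 elements (80% T2D) across 50 signals,
  exactly one causal SNP (Δ = 1.5 log2) planted per signal, all three
  conditions. Reported: single-candidate classification rate and
  causal-identity accuracy among detected-functional signals, plus the
  active-element fraction.

These problem sizes keep each study in the seconds-to-a-minute range on a
single core while leaving Monte-Carlo noise well below the margins being
checked.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| fdr_activity | 0.01 | BH threshold for active calls |
| fdr_skew | 0.10 | BH threshold for allelic skew |
| fdr_response | 0.01 | BH threshold for Tg-vs-DMSO classes |
| r2_min | 0.8 | LD membership threshold for signals |
| bonferroni_locus | 0.01 | per-locus eQTL significance cutoff |
| pseudocount | 1.0 | plasmid-scale units added before log2 ratios |
| dispersion_shrink | 0.5 | weight of the dispersion trend (λ) |
| one_sided_activity | False | one-sided Wald alternative |
| fdr_method | fdr_bh | `fdr_by` switches to Benjamini–Yekutieli |
| dna_dispersion | 0.01 | technical NB dispersion of plasmid samples |
| barcode offset | 0 | barcode position within the read |

## Design choices where the design was open

* Whether normalization pools plasmid and RNA samples: joint within batch
  (configurable via the `sf` argument of the testing functions).
* The FDR procedure is BH; Benjamini–Yekutieli is a config switch.
* Skew BH is applied per condition, not jointly across conditions.
* The Tg-vs-DMSO contrast uses the paired t on log-ratio differences,
  matching the skew test's design on the same five paired replicates; an
  NB interaction model would be a reasonable alternative and the module
  boundary leaves room for it.
* Activity means activation only (β̂ > 0): active sequences are defined by
  higher RNA representation than input, and depletion is biologically a
  different phenomenon (silencing/instability).
* One plasmid sequencing replicate per batch is the simulator default;
  the replicate count is configurable and the reference configurations
  use five (see above).

## Known limitations

* The Wald test with plug-in shrunken dispersions is slightly liberal at
  very small replicate counts; the null false-call rate stays well inside
  the stated bounds but is not an exact test.
* Exact invariance of β̂ under rescaling one sample's counts is impossible
  for a count likelihood (the rescaled sample genuinely carries more
  information); the median-of-ratios size factor absorbs the rescaling
  exactly and the estimates move only within a small fraction of their
  standard errors.
* Skew eligibility (≥1 allele active) induces a winner's-curse selection
  on borderline-active sequences; with very few eligible contrasts the
  within-condition BH has little to average over, which is why the null
  study reports false calls per library contrast.
* The paired t assumes approximately normal log-ratio differences; with
  dispersions near the top of the default range and only five replicates
  its tails are mildly anticonservative, visible as empirical skew FDR
  slightly above the nominal 10% (but within the stated margin).
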