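"""Simulate a complete MPRA experiment with known ground truth.

Builds a small oligo library (200 bp elements carrying SNP alleles in the
three design categories), pairs barcodes to oligos, and draws negative-
binomial barcode counts for plasmid-input and RNA samples in all three
culture conditions.
"""

from mprakit import (default_sample_sheet, simulate_barcode_map,
                     simulate_counts, simulate_library, simulate_truth)

library = simulate_library(n_elements=100, category_props=(0.38, 0.29, 0.33),
                           n_signals=10, frac_two_snp=0.05, seed=7)
truth = simulate_truth(library, frac_active=0.3, activity_log2fc=1.5, seed=7)
barcode_map = simulate_barcode_map(library, barcodes_per_oligo=30,
                                   ambiguous_rate=0.02, seed=7)
samples = default_sample_sheet(n_rna=5, n_dna=5)
counts = simulate_counts(library, barcode_map, truth, samples,
                         depth=500_000, seed=7)

print(f"library: {library['element_id'].nunique()} elements, "
      f"{len(library)} oligos (allele combinations)")
print(library["category"].value_counts().to_string())
print(f"barcodes: {len(barcode_map)} total, "
      f"{int(barcode_map['ambiguous'].sum())} ambiguous (discarded downstream)")
print(f"truly active elements: {int(truth.elements['true_active'].sum())}")
print(f"truly skewed SNPs:     {int(truth.snps['true_skew'].sum())}")
print(f"count matrix: {counts.shape[0]} barcodes x {counts.shape[1]} samples, "
      f"mean barcode count {counts.to_numpy().mean():.1f}")
# Each RNA sample's counts are NB draws whose means carry the planted
# activity (2^1.5 for active oligos) on top of the plasmid abundances.
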