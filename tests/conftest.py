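import numpy as np
import pandas as pd
import pytest

from mprakit import (PipelineConfig, default_sample_sheet, simulate_barcode_map,
                     simulate_counts, simulate_library, simulate_truth)


@pytest.fixture(scope="session")
def small_library():
    return simulate_library(n_elements=40, category_props=(0.4, 0.3, 0.3),
                            n_signals=5, frac_two_snp=0.2, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_library):
    """A compact simulated experiment shared by downstream-module tests:
    30 barcodes/oligo, 5 RNA replicates per condition, 5 technical plasmid
    replicates per batch (deep plasmid measurement)."""
    library = small_library
    truth = simulate_truth(library, frac_active=0.4, seed=11)
    bcmap = simulate_barcode_map(library, barcodes_per_oligo=30,
                                 ambiguous_rate=0.02, seed=11)
    samples = default_sample_sheet(n_rna=5, n_dna=5)
    counts = simulate_counts(library, bcmap, truth, samples,
                             depth=300_000, seed=11)
    return {"library": library, "truth": truth, "bcmap": bcmap,
            "samples": samples, "barcode_counts": counts}


@pytest.fixture(scope="session")
def oligo_counts(small_experiment):
    from mprakit import BarcodeAssignment, aggregate_counts
    assignment = BarcodeAssignment.from_frame(small_experiment["bcmap"])
    counts, n_bc = aggregate_counts(small_experiment["barcode_counts"], assignment,
                                    oligo_ids=list(small_experiment["library"]["oligo_id"]))
    return counts
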