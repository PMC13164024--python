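"""Shared paths and loader for the analysis drivers.

The drivers run in order (01 simulates the cohort the rest analyse) and
write their tables under ``results/``.  Re-running 01 with the same seed
reproduces everything downstream.
"""

from pathlib import Path

SEED = 20260926  # cohort seed used throughout the analysis
CV_SEED = 1      # fold seed for the cross-validated scores

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
INPUTS = RESULTS / "inputs"


def load_cohort():
    """Read the simulated cohort written by 01_simulate_cohort.py."""
    from burdencif.io_cohort import (
        read_annotations,
        read_genotypes,
        read_phenotypes,
        read_regions,
    )

    if not (INPUTS / "phenotypes.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    subjects = read_phenotypes(INPUTS / "phenotypes.csv")
    annotations = read_annotations(INPUTS / "annotations.csv")
    regions = read_regions(INPUTS / "regions.bed")
    G = read_genotypes(INPUTS / "genotypes.tsv",
                       subjects=[s.subject_id for s in subjects])
    return subjects, G, annotations, regions


def analysis_frames():
    """Dataset + score tables shared by drivers 04-06 (recomputed, cheap)."""
    import numpy as np

    from burdencif.burden_scores import (
        collapse_blocks,
        compute_scores,
        estimate_weights,
        ld_blocks,
    )
    from burdencif.io_cohort import build_dataset, filter_region_variants

    subjects, G_all, annotations, regions = load_cohort()
    data = build_dataset(subjects, "by_cause")
    in_region = filter_region_variants(annotations, regions)
    anns = [a for a in in_region if a.variant_class == "non_causative"]
    G = G_all.subset_variants([a.variant_id for a in anns])
    ld = ld_blocks(G, anns)
    Gc, ann_c = collapse_blocks(G, ld, anns)
    weights = estimate_weights(Gc, data, ann_c, cluster=data.cluster)
    scores = compute_scores(Gc, weights, ann_c)
    return subjects, data, Gc, ann_c, weights, scores
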