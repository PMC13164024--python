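"""Cross-validated burden scores.

The variant weights are effect estimates from the same cohort the scores
are evaluated in, so the primary scores are in-sample.  As a robustness
device the cohort is split into five folds stratified by diagnostic
status (AD, FTD, presymptomatic); each fold's scores are computed with
weights estimated on the other four folds only, and the concatenated
out-of-fold scores are standardized once and fed to the interaction
models.  LD blocks are fixed from the full cohort: block structure is a
genotype-only quantity, so re-deriving it per fold would churn column
identity without preventing any outcome leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden_scores import (
    SCORE_NAMES,
    BurdenScores,
    compute_scores,
    estimate_weights,
)

logger = logging.getLogger(__name__)

__all__ = ["FoldAssignment", "make_folds", "cv_scores"]


@dataclass
class FoldAssignment:
    """Fold label (1..k) per subject, stratified by diagnosis."""

    subject_id: np.ndarray
    fold: np.ndarray
    k: int
    seed: int
    strata: np.ndarray

    def __post_init__(self):
        for s in np.unique(self.strata):
            sizes = np.bincount(self.fold[self.strata == s], minlength=self.k + 1)[1:]
            if sizes.max() - sizes.min() > 1:
                raise ValueError(f"unbalanced folds within stratum {s!r}")


def make_folds(subject_ids, strata, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random k-fold split, balanced within each stratum.

    Within every stratum the subjects are randomly permuted and dealt
    into k folds whose sizes differ by at most one.  Deterministic given
    the seed.  Strata smaller than k are still dealt out (some folds
    simply receive none of that stratum), with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    subject_ids = np.asarray(subject_ids)
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    fold = np.zeros(len(subject_ids), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < k:
            warnings.warn(
                f"stratum {s!r} has {len(idx)} subjects (< {k} folds)",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        # deal into folds round-robin, starting fold rotated per stratum
        fold[perm] = 1 + (np.arange(len(perm)) % k)
    return FoldAssignment(subject_id=subject_ids, fold=fold, k=k, seed=seed,
                          strata=strata)


def cv_scores(
    G,
    data,
    folds: FoldAssignment,
    annotations,
    cluster=None,
) -> tuple[BurdenScores, pd.DataFrame]:
    """Out-of-fold burden scores.

    For each fold f the weights are estimated (univariate Fine-Gray per
    column and cause) on the subjects outside f, and the scores of the
    subjects in f are computed with those weights.  A training split
    with no events of some cause yields all-zero weights for that cause
    in that fold, flagged in the returned fold log.  The concatenated
    scores preserve the input subject order.

    Returns ``(BurdenScores, fold_log)``.
    """
    if not np.array_equal(np.sort(np.unique(folds.fold)),
                          np.arange(1, folds.k + 1)):
        missing = set(range(1, folds.k + 1)) - set(folds.fold)
        raise ValueError(f"folds {missing} are empty")
    if len(folds.fold) != len(data):
        raise ValueError("fold assignment does not cover the dataset")

    n = len(data)
    out = pd.DataFrame(np.zeros((n, len(SCORE_NAMES))), columns=list(SCORE_NAMES))
    log_rows = []
    cluster = np.asarray(cluster) if cluster is not None else None
    for f in range(1, folds.k + 1):
        test = folds.fold == f
        train = ~test
        train_data = data.subset(train)
        G_train = _subset_rows(G, train)
        G_test = _subset_rows(G, test)
        for cause in (1, 2):
            if not np.any(train_data.event == cause):
                warnings.warn(
                    f"fold {f}: training split has no events of cause {cause}; "
                    "its weights are all zero",
                    stacklevel=2,
                )
        wt = estimate_weights(
            G_train, train_data, annotations,
            cluster=cluster[train] if cluster is not None else None,
        )
        sc = compute_scores(G_test, wt, annotations)
        out.loc[test, :] = sc.scores.to_numpy()
        log_rows.append(
            {
                "fold": f,
                "n_train": int(train.sum()),
                "n_test": int(test.sum()),
                "n_estimable_ad": int(wt.table.estimable_ad.sum()),
                "n_estimable_ftd": int(wt.table.estimable_ftd.sum()),
            }
        )
    scores = BurdenScores(subjects=np.asarray(G.subjects), scores=out)
    return scores, pd.DataFrame(log_rows)


def _subset_rows(G, mask):
    from .io_cohort import GenotypeMatrix

    mask = np.asarray(mask)
    sub = type(G).__new__(type(G))
    sub.subjects = [s for s, m in zip(G.subjects, mask) if m]
    sub.variants = list(G.variants)
    sub.dosage = G.dosage[mask]
    sub.missing = G.missing[mask]
    return sub
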