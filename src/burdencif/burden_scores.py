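"""Event-specific weighted genetic burden scores.

Each retained non-causative variant gets two weights: its univariate
Fine-Gray coefficient for AD incidence and for FTD incidence.  A subject's
burden score is the dosage-weighted sum

    S_i = sum_j G_ij * beta_j

restricted to one gene set (AD genes or FTD genes) and one weighting
cause, giving four scores per subject.  Variants whose coefficient is not
estimable (e.g. monomorphic among subjects experiencing the cause) carry
weight exactly zero — a conservative fallback, not a dropped variant.

Variants in strong linkage disequilibrium (pairwise dosage r^2 above a
threshold, within one gene) are collapsed to a single pseudo-variant
whose dosage is the unweighted sum of its members before any weight is
estimated; the collapsed column then receives its own pair of weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .competing_risks import fit_fine_gray
from .io_cohort import AD_GENES, GenotypeMatrix, VariantAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "LDMatrix",
    "WeightTable",
    "BurdenScores",
    "SCORE_NAMES",
    "ld_blocks",
    "collapse_blocks",
    "estimate_weights",
    "compute_scores",
    "dichotomize",
    "standardize_iqr",
]

#: the four scores: <gene set>_w_<weighting cause>
SCORE_NAMES = ("ad_w_ad", "ad_w_ftd", "ftd_w_ad", "ftd_w_ftd")


@dataclass
class LDMatrix:
    """Pairwise squared dosage correlations and the derived blocks.

    ``blocks`` are the connected components (within a single gene) of the
    graph linking variant pairs with r^2 >= threshold; singletons are not
    blocks.
    """

    variants: list
    r2: np.ndarray
    blocks: list
    threshold: float

    def block_of(self, variant_id: str) -> Optional[int]:
        for bi, b in enumerate(self.blocks):
            if variant_id in b:
                return bi
        return None


@dataclass
class WeightTable:
    """Per-column (variant or LD block) Fine-Gray weights for both causes."""

    table: pd.DataFrame  # variant_id, gene, beta_ad, beta_ftd, estimable_*, source

    def __post_init__(self):
        req = {"variant_id", "gene", "beta_ad", "beta_ftd",
               "estimable_ad", "estimable_ftd", "source"}
        if not req <= set(self.table.columns):
            raise ValueError(f"weight table lacks columns {req - set(self.table.columns)}")
        bad_ad = self.table.loc[~self.table.estimable_ad, "beta_ad"]
        bad_ftd = self.table.loc[~self.table.estimable_ftd, "beta_ftd"]
        if not (np.all(bad_ad == 0.0) and np.all(bad_ftd == 0.0)):
            raise ValueError("non-estimable weights must be exactly zero")

    def weights(self, cause: str) -> pd.Series:
        return self.table.set_index("variant_id")[f"beta_{cause}"]


@dataclass
class BurdenScores:
    """The four per-subject burden scores (raw scale)."""

    subjects: np.ndarray
    scores: pd.DataFrame  # columns = SCORE_NAMES

    def __post_init__(self):
        missing = set(SCORE_NAMES) - set(self.scores.columns)
        if missing:
            raise ValueError(f"missing score columns {missing}")
        if len(self.scores) != len(self.subjects):
            raise ValueError("score rows do not match subject ids")

    def standardized(self, lower: float = 20.0, upper: float = 80.0) -> pd.DataFrame:
        return self.scores.apply(lambda c: standardize_iqr(c, lower, upper))

    def dichotomized(self) -> pd.DataFrame:
        return self.scores.apply(dichotomize)


def ld_blocks(
    G: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    r2_threshold: float = 0.8,
) -> LDMatrix:
    """Pairwise dosage r^2 and within-gene LD blocks.

    r^2 is the squared Pearson correlation of dosage vectors over
    pairwise-complete observations.  A zero-variance variant has r^2
    defined as 0 against all others.  Blocks are connected components of
    the r^2 >= threshold graph restricted to pairs in the same gene.
    """
    if len(G.variants) < 2:
        raise ValueError("need at least two variants for LD analysis")
    gene_of = {a.variant_id: a.gene for a in annotations}
    X = np.where(G.missing, np.nan, G.dosage)
    p = X.shape[1]
    r2 = np.zeros((p, p))
    np.fill_diagonal(r2, 1.0)
    sd = np.nanstd(X, axis=0)
    for j in range(p):
        if sd[j] == 0:
            logger.info("variant %s has zero dosage variance", G.variants[j])
    for j in range(p):
        for l in range(j + 1, p):
            both = ~np.isnan(X[:, j]) & ~np.isnan(X[:, l])
            if both.sum() < 2:
                continue
            xj, xl = X[both, j], X[both, l]
            if xj.std() == 0 or xl.std() == 0:
                continue
            r = np.corrcoef(xj, xl)[0, 1]
            r2[j, l] = r2[l, j] = r * r

    # union-find over same-gene high-LD pairs
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(p):
        for l in range(j + 1, p):
            if r2[j, l] >= r2_threshold and (
                gene_of.get(G.variants[j]) == gene_of.get(G.variants[l])
            ):
                parent[find(j)] = find(l)
    comp: dict[int, list] = {}
    for j in range(p):
        comp.setdefault(find(j), []).append(G.variants[j])
    blocks = [sorted(v) for v in comp.values() if len(v) > 1]
    blocks.sort(key=lambda b: b[0])
    return LDMatrix(variants=list(G.variants), r2=r2, blocks=blocks,
                    threshold=r2_threshold)


def collapse_blocks(
    G: GenotypeMatrix,
    ld: LDMatrix,
    annotations: Optional[Sequence[VariantAnnotation]] = None,
):
    """Replace each LD block by one pseudo-variant (unweighted dosage sum).

    Non-block variants pass through unchanged, in their input order; each
    pseudo-variant takes the position of its first member.  Returns
    ``(GenotypeMatrix, annotations)`` where the pseudo-variant inherits
    the gene of its members.  Pseudo-variant dosages may exceed 2, so the
    result is returned as plain arrays inside a lightweight matrix that
    skips the 0/1/2 check.
    """
    in_block = {v: bi for bi, b in enumerate(ld.blocks) for v in b}
    ann_by_id = {a.variant_id: a for a in (annotations or [])}
    X = np.where(G.missing, np.nan, G.dosage)
    cols, ids, new_ann = [], [], []
    done_blocks = set()
    for j, v in enumerate(G.variants):
        bi = in_block.get(v)
        if bi is None:
            cols.append(X[:, j])
            ids.append(v)
            if v in ann_by_id:
                new_ann.append(ann_by_id[v])
        elif bi not in done_blocks:
            done_blocks.add(bi)
            members = [G.variants.index(m) for m in ld.blocks[bi]]
            cols.append(np.nansum(X[:, members], axis=1))
            bid = f"block_{'_'.join(ld.blocks[bi])}"
            ids.append(bid)
            if ld.blocks[bi][0] in ann_by_id:
                a0 = ann_by_id[ld.blocks[bi][0]]
                new_ann.append(
                    VariantAnnotation(
                        variant_id=bid, gene=a0.gene, chrom=a0.chrom,
                        pos=a0.pos, variant_class=a0.variant_class,
                    )
                )
    dosage = np.column_stack(cols)
    out = _CollapsedMatrix(subjects=list(G.subjects), variants=ids, dosage=dosage)
    return (out, new_ann) if annotations is not None else (out, None)


@dataclass
class _CollapsedMatrix:
    """Dosage matrix after block collapsing (sums may exceed 2)."""

    subjects: list
    variants: list
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing = np.isnan(self.dosage)

    def imputed(self) -> np.ndarray:
        out = self.dosage.copy()
        for j in range(out.shape[1]):
            m = self.missing[:, j]
            if m.any():
                out[m, j] = out[~m, j].mean() if (~m).any() else 0.0
        return out


def estimate_weights(
    G,
    data,
    annotations: Sequence[VariantAnnotation],
    cluster=None,
) -> WeightTable:
    """Univariate Fine-Gray coefficient of each column, per cause.

    ``G`` must contain only non-causative columns (causative and VUS
    variants are excluded upstream); a causative or VUS annotation here
    raises.  Non-estimable or non-converged fits yield weight 0 with the
    corresponding flag cleared.
    """
    ann_by_id = {a.variant_id: a for a in annotations}
    for v in G.variants:
        a = ann_by_id.get(v)
        if a is not None and a.variant_class != "non_causative":
            raise ValueError(f"variant {v} is {a.variant_class}; scores use "
                             "non-causative variants only")
    X = G.imputed()
    rows = []
    for j, v in enumerate(G.variants):
        row = {"variant_id": v,
               "gene": ann_by_id[v].gene if v in ann_by_id else "",
               "source": "ld_block" if v.startswith("block_") else "single_variant"}
        for cause, key in ((1, "ad"), (2, "ftd")):
            beta, ok = 0.0, False
            try:
                fit = fit_fine_gray(
                    data, pd.DataFrame({v: X[:, j]}), cause=cause, cluster=cluster
                )
                if fit.converged and fit.estimable[0] and np.isfinite(fit.coef[0]):
                    beta, ok = float(fit.coef[0]), True
            except ValueError:
                pass
            row[f"beta_{key}"] = beta if ok else 0.0
            row[f"estimable_{key}"] = ok
        rows.append(row)
    return WeightTable(pd.DataFrame(rows))


def compute_scores(
    G,
    weights: WeightTable,
    annotations: Sequence[VariantAnnotation],
) -> BurdenScores:
    """The four dosage-weighted burden scores.

    Scores are formed by restricting the weighted sum to (gene set,
    weighting cause) pairs: AD genes weighted by the AD coefficients and
    by the FTD coefficients, and likewise for FTD genes.
    """
    wt = weights.table.set_index("variant_id")
    missing = [v for v in G.variants if v not in wt.index]
    if missing:
        raise ValueError(f"weight table does not cover columns {missing[:5]}")
    gene_of = {a.variant_id: a.gene for a in annotations}
    X = G.imputed()
    is_ad_gene = np.array(
        [gene_of.get(v, wt.loc[v, "gene"]) in AD_GENES for v in G.variants]
    )
    b_ad = wt.loc[G.variants, "beta_ad"].to_numpy(dtype=float)
    b_ftd = wt.loc[G.variants, "beta_ftd"].to_numpy(dtype=float)
    # accumulate column by column in input order: bitwise-reproducible by a
    # plain per-subject loop over variants (BLAS dot products are not)
    acc = {k: np.zeros(X.shape[0]) for k in SCORE_NAMES}
    for j in range(X.shape[1]):
        gs = "ad" if is_ad_gene[j] else "ftd"
        acc[f"{gs}_w_ad"] += X[:, j] * b_ad[j]
        acc[f"{gs}_w_ftd"] += X[:, j] * b_ftd[j]
    scores = pd.DataFrame(acc, columns=list(SCORE_NAMES))
    return BurdenScores(subjects=np.asarray(G.subjects), scores=scores)


def dichotomize(values, reference=None) -> np.ndarray:
    """Median split: 1 (high) strictly above the median, 0 otherwise.

    ``reference`` supplies the population whose median is used (defaults
    to ``values`` itself — the full analysis cohort).
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    if len(np.unique(ref)) < 2:
        raise ValueError("cannot dichotomize a constant score")
    med = np.quantile(ref, 0.5)  # linear-interpolation quantile
    return (values > med).astype(int)


def standardize_iqr(values, lower: float = 20.0, upper: float = 80.0):
    """Center at the mean and scale by the P80 - P20 spread.

    After standardization a one-unit contrast compares a subject at the
    80th percentile of the raw score with one at the 20th.
    """
    arr = np.asarray(values, dtype=float)
    p_lo, p_hi = np.quantile(arr, [lower / 100.0, upper / 100.0])
    if p_hi <= p_lo:
        raise ValueError(
            f"degenerate spread: P{upper:g} equals P{lower:g} ({p_hi:g})"
        )
    out = (arr - arr.mean()) / (p_hi - p_lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
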