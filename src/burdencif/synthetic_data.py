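"""Synthetic family-clustered competing-risks cohorts.

Generates genotypes, an LD block, and AD/FTD onset ages under a law whose
cause-1 subdistribution follows proportional subdistribution hazards, so
Fine-Gray regression on simulated data is estimating a true, known
coefficient.  The construction (direct subdistribution simulation):

* with linear predictors eta_1 = G beta_1 + u_f and eta_2 = G beta_2 + u_f
  (u_f a shared family frailty), the event is cause 1 with probability
  1 - (1 - p1)^exp(eta_1);
* given cause 1, the latent time solves
  F_1(t | eta_1) = [1 - (1 - p1 (1 - e^{-lambda1 t}))^exp(eta_1)] / [1 - (1 - p1)^exp(eta_1)]
  by closed-form inversion, which makes the marginal cause-1
  subdistribution hazard proportional to exp(eta_1);
* given cause 2, the latent time is Exponential(lambda2 * exp(eta_2));
* an independent Uniform(c_lo, c_hi) censoring time is applied, and all
  times are shifted by ``age_offset`` onto an age-in-years scale.

The family frailty induces within-family outcome correlation and is a
stress test for the cluster-robust variance; the fitted models never see
it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_cohort import (
    AD_GENES,
    FTD_GENES,
    CompetingRisksDataset,
    GenotypeMatrix,
    SubjectRecord,
    VariantAnnotation,
)

__all__ = [
    "VariantSpec",
    "SimulationParams",
    "CohortBundle",
    "simulate_genotypes",
    "simulate_onset",
    "simulate_study_cohort",
    "STUDY_VARIANT_COUNTS",
]

#: non-causative variant counts per gene in the study-like preset
STUDY_VARIANT_COUNTS = {
    "APP": 3, "PSEN1": 7, "PSEN2": 12, "MAPT": 22, "GRN": 16, "C9orf72": 4,
}

_GENE_CHROM = {
    "APP": "21", "PSEN1": "14", "PSEN2": "1",
    "MAPT": "17", "GRN": "17", "C9orf72": "9",
}
_GENE_START = {  # synthetic coordinates, spaced so regions never overlap
    "APP": 1_000_000, "PSEN1": 2_000_000, "PSEN2": 3_000_000,
    "MAPT": 4_000_000, "GRN": 6_000_000, "C9orf72": 8_000_000,
}


@dataclass
class VariantSpec:
    variant_id: str
    gene: str
    maf: float
    beta1: float = 0.0  # effect on the cause-1 (AD) subdistribution predictor
    beta2: float = 0.0  # effect on the cause-2 (FTD) predictor
    variant_class: str = "non_causative"

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.variant_id}: MAF must be in (0, 0.5]")


@dataclass
class SimulationParams:
    """Study conditions for one simulated stratum."""

    n_families: int
    variant_specs: list
    family_size_mean: float = 3.0          # truncated Poisson, >= 1
    ld_block: Optional[dict] = None        # {"members": [ids], "flip_prob": p}
    p1: float = 0.25                       # baseline cause-1 mass
    lambda1: float = 1.0 / 16.0            # 1/years
    lambda2: float = 1.0 / 25.0
    frailty_sd: float = 0.3
    censor_window: tuple = (0.0, 60.0)     # years, on the latent scale
    age_offset: float = 35.0               # years added to latent times
    seed: int = 0
    n_subjects: Optional[int] = None       # trim/pad family draw to this total

    def __post_init__(self):
        if not (0.0 < self.p1 < 1.0):
            raise ValueError("p1 must be in (0, 1)")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("rate parameters must be positive")
        if not self.censor_window[0] < self.censor_window[1]:
            raise ValueError("censoring window must have c_lo < c_hi")


def _family_sizes(params: SimulationParams, rng) -> np.ndarray:
    sizes = 1 + rng.poisson(max(params.family_size_mean - 1.0, 0.0),
                            size=params.n_families)
    if params.n_subjects is not None:
        total = int(sizes.sum())
        while total < params.n_subjects:
            sizes = np.append(sizes, 1 + rng.poisson(params.family_size_mean - 1.0))
            total = int(sizes.sum())
        # trim the last families down to the exact target
        excess = total - params.n_subjects
        i = len(sizes) - 1
        while excess > 0:
            cut = min(excess, sizes[i] - 1)
            sizes[i] -= cut
            excess -= cut
            if excess > 0:
                if sizes[i] == 1:
                    sizes = sizes[:i] if excess >= 1 else sizes
                    excess -= 1
                i -= 1
        sizes = sizes[sizes > 0]
    return sizes


def simulate_genotypes(params: SimulationParams, rng=None, id_prefix: str = "S"):
    """Dosage matrix plus annotations for one stratum.

    Non-block variants are independent Binomial(2, MAF) per subject.  An
    LD block is generated by drawing the anchor's two alleles and copying
    them into every member with a per-allele flip probability, which
    yields pairwise r^2 near (1 - 2 flip_prob)^2-ish at low flip rates.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    sizes = _family_sizes(params, rng)
    n = int(sizes.sum())
    subjects = [f"{id_prefix}{i:04d}" for i in range(n)]
    families = np.repeat([f"F{id_prefix}{i:03d}" for i in range(len(sizes))], sizes)

    specs = params.variant_specs
    block = params.ld_block or {}
    members = set(block.get("members", []))
    flip = float(block.get("flip_prob", 0.01))
    anchor_alleles = None
    cols = {}
    for spec in specs:
        if spec.variant_id in members:
            if anchor_alleles is None:
                anchor_alleles = rng.binomial(1, spec.maf, size=(n, 2))
                cols[spec.variant_id] = anchor_alleles.sum(axis=1)
            else:
                flips = rng.binomial(1, flip, size=(n, 2))
                cols[spec.variant_id] = np.abs(anchor_alleles - flips).sum(axis=1)
        else:
            cols[spec.variant_id] = rng.binomial(2, spec.maf, size=n)
    dosage = np.column_stack([cols[s.variant_id] for s in specs]).astype(float)

    pos_counter: dict[str, int] = {}
    annotations = []
    for spec in specs:
        k = pos_counter.get(spec.gene, 0)
        pos_counter[spec.gene] = k + 1
        annotations.append(
            VariantAnnotation(
                variant_id=spec.variant_id,
                gene=spec.gene,
                chrom=_GENE_CHROM[spec.gene],
                pos=_GENE_START[spec.gene] + 500 * (k + 1),
                ref="A",
                alt="G",
                variant_class=spec.variant_class,
            )
        )
    G = GenotypeMatrix(subjects=subjects, variants=[s.variant_id for s in specs],
                       dosage=dosage)
    return G, annotations, families


def simulate_onset(
    params: SimulationParams,
    G: GenotypeMatrix,
    families: Optional[np.ndarray] = None,
    rng=None,
) -> CompetingRisksDataset:
    """Competing event times for the subjects of ``G`` under the stated law."""
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    n = len(G.subjects)
    if families is None:
        families = np.asarray([f"F{i}" for i in range(n)])
    beta1 = np.array([s.beta1 for s in params.variant_specs])
    beta2 = np.array([s.beta2 for s in params.variant_specs])
    X = G.imputed()
    # center predictors at the expected dosage so p1/lambda describe a
    # subject with an average genotype; coefficients are unchanged
    X = X - 2.0 * np.array([s.maf for s in params.variant_specs])

    fam_labels, fam_inverse = np.unique(families, return_inverse=True)
    u = (rng.normal(0.0, params.frailty_sd, size=len(fam_labels))
         if params.frailty_sd > 0 else np.zeros(len(fam_labels)))
    eta1 = X @ beta1 + u[fam_inverse]
    eta2 = X @ beta2 + u[fam_inverse]

    e1 = np.exp(eta1)
    p1 = params.p1
    p_cause1 = 1.0 - (1.0 - p1) ** e1
    is1 = rng.uniform(size=n) < p_cause1

    latent = np.empty(n)
    # cause 1: closed-form inverse of the conditional subdistribution CDF
    uu = rng.uniform(size=n)
    B = p_cause1
    inner = (1.0 - uu * B) ** (1.0 / e1)       # in (1 - p1, 1)
    t1 = -np.log(1.0 - (1.0 - inner) / p1) / params.lambda1
    # cause 2: exponential with rate lambda2 * exp(eta2)
    t2 = rng.exponential(1.0, size=n) / (params.lambda2 * np.exp(eta2))
    latent = np.where(is1, t1, t2)
    cause = np.where(is1, 1, 2)

    c_lo, c_hi = params.censor_window
    cens = rng.uniform(c_lo, c_hi, size=n)
    observed = np.minimum(latent, cens)
    event = np.where(latent <= cens, cause, 0)
    time = params.age_offset + observed
    return CompetingRisksDataset(
        subject_id=np.asarray(G.subjects),
        time=time,
        event=event,
        cluster=families,
    )


@dataclass
class CohortBundle:
    """Everything the pipeline reads, as in-memory objects."""

    subjects: list
    genotypes: GenotypeMatrix
    annotations: list
    regions: pd.DataFrame
    families: np.ndarray

    def write(self, outdir) -> dict:
        from pathlib import Path

        from .io_cohort import (
            write_annotations,
            write_genotypes_tsv,
            write_phenotypes,
        )

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / "phenotypes.csv",
            "genotypes": outdir / "genotypes.tsv",
            "annotations": outdir / "annotations.csv",
            "regions": outdir / "regions.bed",
        }
        write_phenotypes(self.subjects, paths["phenotypes"])
        write_genotypes_tsv(self.genotypes, paths["genotypes"])
        write_annotations(self.annotations, paths["annotations"])
        self.regions.to_csv(paths["regions"], sep="\t", header=False, index=False)
        return paths


def _study_variant_specs(rng) -> list:
    """64 non-causative variants (3/7/12/22/16/4 per gene) plus causative
    and VUS decoys used to exercise the exclusion rules."""
    mafs = [0.05, 0.1, 0.2, 0.3]
    specs = []
    idx = 0
    for gene, count in STUDY_VARIANT_COUNTS.items():
        ad = gene in AD_GENES
        for k in range(count):
            # every third variant carries a real effect on "its" cause and
            # a weaker one on the other, mimicking partially shared risk
            hit = k % 3 == 0
            b_own = 0.35 if hit else 0.0
            b_other = 0.15 if (hit and k % 6 == 0) else 0.0
            specs.append(
                VariantSpec(
                    variant_id=f"{gene}_v{k + 1}",
                    gene=gene,
                    maf=mafs[idx % len(mafs)],
                    beta1=b_own if ad else b_other,
                    beta2=b_other if ad else b_own,
                )
            )
            idx += 1
    for gene in STUDY_VARIANT_COUNTS:
        specs.append(
            VariantSpec(
                variant_id=f"{gene}_causative", gene=gene, maf=0.05,
                variant_class="causative",
            )
        )
    specs.append(VariantSpec("PSEN2_vus1", "PSEN2", 0.05, variant_class="VUS"))
    specs.append(VariantSpec("GRN_vus1", "GRN", 0.05, variant_class="VUS"))
    return specs


#: cohort composition mirrored from the study: families per causative-gene
#: group sized so the six groups hold 39/71/13/29/188/86 subjects
_GROUP_SIZES = {
    "APP": 39, "PSEN1": 71, "PSEN2": 13, "MAPT": 29, "GRN": 188, "C9orf72": 86,
}

#: per-stratum event law: carriers of an AD-gene causative variant almost
#: always fail from AD (cause 1) and vice versa
_STRATUM_LAW = {
    "AD": dict(p1=0.97, lambda1=1.0 / 12.0, lambda2=1.0 / 18.0,
               censor_window=(0.0, 55.0), age_offset=40.0),
    "FTD": dict(p1=0.03, lambda1=1.0 / 12.0, lambda2=1.0 / 18.0,
                censor_window=(0.0, 75.0), age_offset=42.0),
}


def simulate_study_cohort(seed: int = 0) -> CohortBundle:
    """A 426-subject cohort with the study's shape.

    Six causative-gene groups (39/71/13/29/188/86 subjects in family
    clusters), 64 non-causative variants with one six-variant PSEN1 LD
    block, AD/FTD/censored mix near 93/226/107, onset ages in plausible
    adult ranges, APOE e4 carriage near 79/426.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    specs = _study_variant_specs(rng)
    block_members = [f"PSEN1_v{k}" for k in range(1, 7)]

    all_records: list[SubjectRecord] = []
    g_parts, fam_parts = [], []
    annotations = None
    for gene, size in _GROUP_SIZES.items():
        stratum = "AD" if gene in AD_GENES else "FTD"
        law = _STRATUM_LAW[stratum]
        params = SimulationParams(
            n_families=max(size // 3, 1),
            n_subjects=size,
            variant_specs=specs,
            ld_block={"members": block_members, "flip_prob": 0.01},
            frailty_sd=0.3,
            seed=seed,
            **law,
        )
        G, ann, families = simulate_genotypes(params, rng=rng, id_prefix=gene[:2])
        annotations = ann  # identical across strata
        families = np.array([f"{gene}_{f}" for f in families])
        data = simulate_onset(params, G, families=families, rng=rng)
        subjects = [f"{gene}_{s}" for s in G.subjects]
        G = GenotypeMatrix(subjects=subjects, variants=G.variants, dosage=G.dosage,
                           missing=G.missing)
        g_parts.append(G)
        fam_parts.append(families)
        for i, sid in enumerate(subjects):
            ev = int(data.event[i])
            t = float(data.time[i])
            diagnosis = {0: "presymptomatic", 1: "AD", 2: "FTD"}[ev]
            followup_pad = float(rng.uniform(0.0, 2.0))
            all_records.append(
                SubjectRecord(
                    subject_id=sid,
                    family_id=str(families[i]),
                    sex="F" if rng.uniform() < 0.47 else "M",
                    diagnosis=diagnosis,
                    age_onset=t if ev else None,
                    age_last_followup=t + followup_pad if ev else t,
                    causative_gene=gene,
                    causative_class="pathogenic" if rng.uniform() < 0.9 else "VUS",
                    apoe_e4=bool(rng.uniform() < 79 / 426),
                )
            )

    genotypes = GenotypeMatrix(
        subjects=[s for g in g_parts for s in g.subjects],
        variants=g_parts[0].variants,
        dosage=np.vstack([g.dosage for g in g_parts]),
    )
    regions = pd.DataFrame(
        [
            {
                "chrom": _GENE_CHROM[g],
                "start": _GENE_START[g],
                "end": _GENE_START[g] + 500 * (STUDY_VARIANT_COUNTS[g] + 1),
                "name": g,
            }
            for g in STUDY_VARIANT_COUNTS
        ]
    )
    return CohortBundle(
        subjects=all_records,
        genotypes=genotypes,
        annotations=annotations,
        regions=regions,
        families=np.concatenate(fam_parts),
    )
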