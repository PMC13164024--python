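"""Cohort input/output and dataset construction.

The analysis cohort consists of carriers of causative variants in one of
six dementia genes: APP, PSEN1, PSEN2 (AD genes) and MAPT, GRN, C9orf72
(FTD genes).  Each subject is either affected (AD or FTD, with an age at
onset) or presymptomatic (censored at the age of last follow-up).  The
time scale of every analysis is age in years with no delayed entry.

Files read here are plain text: a delimited phenotype table, a genotype
matrix (subjects x variants TSV of 0/1/2 dosages, or a VCF), a variant
annotation table and a BED file of gene regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AD_GENES = ("APP", "PSEN1", "PSEN2")
FTD_GENES = ("MAPT", "GRN", "C9orf72")
GENES = AD_GENES + FTD_GENES

DIAGNOSES = ("AD", "FTD", "presymptomatic")
VARIANT_CLASSES = ("causative", "VUS", "non_causative")

__all__ = [
    "SubjectRecord",
    "VariantAnnotation",
    "GenotypeMatrix",
    "CompetingRisksDataset",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotations",
    "write_annotations",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_regions",
    "filter_region_variants",
    "build_dataset",
    "AD_GENES",
    "FTD_GENES",
    "GENES",
]


@dataclass
class SubjectRecord:
    """One cohort member.

    ``age_onset`` is required for affected subjects (diagnosis AD or FTD)
    and must be absent for presymptomatic ones, whose contribution is a
    censored observation at ``age_last_followup``.
    """

    subject_id: str
    family_id: str
    sex: str
    diagnosis: str
    age_last_followup: float
    age_onset: Optional[float] = None
    causative_gene: str = ""
    causative_class: str = "pathogenic"
    apoe_e4: Optional[bool] = None

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"subject {self.subject_id}: unknown diagnosis {self.diagnosis!r}"
            )
        if self.causative_gene and self.causative_gene not in GENES:
            raise ValueError(
                f"subject {self.subject_id}: unknown gene {self.causative_gene!r}"
            )
        if self.diagnosis in ("AD", "FTD"):
            if self.age_onset is None or not self.age_onset > 0:
                raise ValueError(
                    f"subject {self.subject_id}: affected but age_onset missing"
                )
        elif self.age_onset is not None:
            raise ValueError(
                f"subject {self.subject_id}: presymptomatic with an onset age"
            )
        if (
            self.age_onset is not None
            and self.age_last_followup is not None
            and not np.isnan(self.age_last_followup)
            and self.age_last_followup < self.age_onset
        ):
            raise ValueError(
                f"subject {self.subject_id}: last follow-up precedes onset"
            )


@dataclass
class VariantAnnotation:
    """Annotation for one variant; ``gene_set`` derives from the gene."""

    variant_id: str
    gene: str
    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str = "N"
    alt: str = "N"
    variant_class: str = "non_causative"

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"variant {self.variant_id}: unknown gene {self.gene!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"variant {self.variant_id}: unknown class {self.variant_class!r}"
            )

    @property
    def gene_set(self) -> str:
        return "AD_genes" if self.gene in AD_GENES else "FTD_genes"


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix, coded 0/1/2 copies of the minor allele.

    ``missing`` masks entries with no genotype call.  ``imputed`` returns
    dosages with missing entries replaced by the variant's observed mean
    (used for score computation; LD uses pairwise-complete values).
    """

    subjects: list
    variants: list
    dosage: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("dosage shape does not match id lists")
        if self.missing is None:
            self.missing = np.zeros(self.dosage.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        obs = self.dosage[~self.missing]
        if obs.size and not np.all(np.isin(obs, (0, 1, 2))):
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    def imputed(self) -> np.ndarray:
        if not self.missing.any():
            return self.dosage.copy()
        out = self.dosage.copy()
        frac = self.missing.mean()
        logger.info("imputing %.2f%% missing genotypes to variant means", 100 * frac)
        for j in range(out.shape[1]):
            m = self.missing[:, j]
            if m.any():
                mean = out[~m, j].mean() if (~m).any() else 0.0
                out[m, j] = mean
        return out

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variants.index(v) for v in variant_ids]
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=list(variant_ids),
            dosage=self.dosage[:, idx],
            missing=self.missing[:, idx],
        )


@dataclass
class CompetingRisksDataset:
    """Per-subject follow-up for the competing-risks analyses.

    ``event`` is 0 = censored, 1 = AD, 2 = FTD (or 0/1 for the composite
    endpoint); ``time`` is age in years; ``cluster`` is the family id.
    """

    subject_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    cluster: np.ndarray
    covariates: pd.DataFrame = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.subject_id = np.asarray(self.subject_id)
        self.cluster = np.asarray(self.cluster)
        if not np.all(self.time > 0):
            raise ValueError("all times must be positive")
        if not np.all(np.isin(self.event, (0, 1, 2))):
            raise ValueError("event codes must be 0, 1 or 2")
        if len({len(self.time), len(self.event), len(self.cluster),
                len(self.subject_id)}) != 1:
            raise ValueError("field lengths differ")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.time)))

    def __len__(self):
        return len(self.time)

    def subset(self, mask) -> "CompetingRisksDataset":
        mask = np.asarray(mask)
        return CompetingRisksDataset(
            subject_id=self.subject_id[mask],
            time=self.time[mask],
            event=self.event[mask],
            cluster=self.cluster[mask],
            covariates=self.covariates.loc[mask].reset_index(drop=True),
        )


_PHENO_COLS = [
    "subject_id", "family_id", "sex", "diagnosis", "age_onset",
    "age_last_followup", "causative_gene", "causative_class", "apoe_e4",
]


def _parse_bool(v):
    if pd.isna(v) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        if v in (0, 1):
            return bool(v)
        raise ValueError(f"cannot parse APOE e4 flag {v!r}")
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "carrier"):
        return True
    if s in ("0", "false", "no", "noncarrier"):
        return False
    raise ValueError(f"cannot parse APOE e4 flag {v!r}")


def read_phenotypes(path) -> list[SubjectRecord]:
    """Read the phenotype table (CSV or TSV, header required).

    Expected columns: subject_id, family_id, sex, diagnosis, age_onset,
    age_last_followup, causative_gene, causative_class, apoe_e4.  Blank
    age_onset means absent.  Raises on any invalid row, naming it.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "family_id": str})
    missing_cols = [c for c in ("subject_id", "diagnosis", "age_last_followup")
                    if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file lacks columns: {missing_cols}")
    records = []
    for i, row in df.iterrows():
        onset = row.get("age_onset")
        onset = None if pd.isna(onset) else float(onset)
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    family_id=str(row.get("family_id", row["subject_id"])),
                    sex=str(row.get("sex", "")),
                    diagnosis=str(row["diagnosis"]),
                    age_onset=onset,
                    age_last_followup=float(row["age_last_followup"]),
                    causative_gene=str(row.get("causative_gene", "") or ""),
                    causative_class=str(row.get("causative_class", "pathogenic")),
                    apoe_e4=_parse_bool(row.get("apoe_e4")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"phenotype row {i}: {exc}") from exc
    return records


def write_phenotypes(records: Sequence[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "family_id": r.family_id,
                "sex": r.sex,
                "diagnosis": r.diagnosis,
                "age_onset": "" if r.age_onset is None else r.age_onset,
                "age_last_followup": r.age_last_followup,
                "causative_gene": r.causative_gene,
                "causative_class": r.causative_class,
                "apoe_e4": "" if r.apoe_e4 is None else int(r.apoe_e4),
            }
        )
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    pd.DataFrame(rows, columns=_PHENO_COLS).to_csv(path, sep=sep, index=False)


def read_annotations(path) -> list[VariantAnnotation]:
    """Read the variant annotation table (columns variant_id, gene, chrom,
    pos, ref, alt, variant_class)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"variant_id": str, "chrom": str})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantAnnotation(
                    variant_id=str(row["variant_id"]),
                    gene=str(row["gene"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row.get("ref", "N")),
                    alt=str(row.get("alt", "N")),
                    variant_class=str(row.get("variant_class", "non_causative")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"annotation row {i}: {exc}") from exc
    return out


def write_annotations(annotations: Sequence[VariantAnnotation], path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    pd.DataFrame(
        [
            {
                "variant_id": a.variant_id, "gene": a.gene, "chrom": a.chrom,
                "pos": a.pos, "ref": a.ref, "alt": a.alt,
                "variant_class": a.variant_class,
            }
            for a in annotations
        ]
    ).to_csv(path, sep=sep, index=False)


def _read_genotypes_vcf(path, annotations, known_subjects):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ann_by_id = {a.variant_id: a for a in annotations}
    variants, columns, missing_cols = [], [], []
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; split it first"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if ann_by_id and vid not in ann_by_id:
            continue
        gts = rec.genotype.array()
        alleles = gts[:, :2]
        miss = np.any(alleles < 0, axis=1)
        dose = np.where(miss, 0, np.clip(alleles, 0, None).sum(axis=1))
        variants.append(vid)
        columns.append(dose.astype(float))
        missing_cols.append(miss)
    dosage = np.column_stack(columns) if columns else np.zeros((len(samples), 0))
    missing = np.column_stack(missing_cols) if missing_cols else np.zeros_like(
        dosage, dtype=bool
    )
    return samples, variants, dosage, missing


def read_genotypes(path, annotations=None, subjects=None) -> GenotypeMatrix:
    """Read genotype dosages from a VCF (.vcf/.vcf.gz) or a TSV.

    The TSV dialect: first column ``subject_id``, remaining columns are
    variant ids, values 0/1/2 or blank/NA for missing.  Subjects present
    in the genotype file but absent from ``subjects`` (when given) are
    dropped with a warning.
    """
    path = Path(path)
    annotations = annotations or []
    if path.suffix in (".vcf", ".gz", ".bcf"):
        samples, variants, dosage, missing = _read_genotypes_vcf(
            path, annotations, subjects
        )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        samples = df["subject_id"].tolist()
        variants = [c for c in df.columns if c != "subject_id"]
        raw = df[variants].to_numpy(dtype=float)
        missing = np.isnan(raw)
        dosage = np.where(missing, 0, raw)
    if subjects is not None:
        known = set(subjects)
        keep = [i for i, s in enumerate(samples) if s in known]
        extra = [s for s in samples if s not in known]
        if extra:
            warnings.warn(
                f"dropping {len(extra)} genotyped subjects absent from the "
                f"phenotype table (e.g. {extra[:3]})",
                stacklevel=2,
            )
        samples = [samples[i] for i in keep]
        dosage = dosage[keep]
        missing = missing[keep]
    return GenotypeMatrix(
        subjects=samples, variants=variants, dosage=dosage, missing=missing
    )


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        np.where(G.missing, np.nan, G.dosage), columns=G.variants
    )
    df.insert(0, "subject_id", G.subjects)
    out = df.copy()
    for c in G.variants:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) of gene regions.

    Returns a DataFrame with columns chrom, start, end, name.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
        dtype={"chrom": str, "name": str},
    )
    return df


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def filter_region_variants(
    annotations: Sequence[VariantAnnotation],
    regions: pd.DataFrame,
    flank: int = 5000,
) -> list[VariantAnnotation]:
    """Keep variants falling in a gene region expanded by ``flank`` bp.

    BED intervals are 0-based half-open; annotation positions are 1-based.
    A variant at 1-based position p is retained for region [s, e) when
    s - flank <= p - 1 < e + flank (flanks clamped at zero).  Input order
    is preserved.  Chromosome names are compared after stripping a
    leading "chr"; a mismatch that empties a chromosome entirely raises.
    """
    reg = regions.copy()
    reg["chrom_n"] = reg["chrom"].map(_norm_chrom)
    ann_chroms = {_norm_chrom(a.chrom) for a in annotations}
    if len(annotations) and not (ann_chroms & set(reg["chrom_n"])):
        raise ValueError(
            "no chromosome overlap between annotations and regions; check "
            "naming ('chr1' vs '1' is normalized, other aliases are not)"
        )
    kept = []
    for a in annotations:
        p0 = a.pos - 1  # to 0-based
        c = _norm_chrom(a.chrom)
        sub = reg[reg["chrom_n"] == c]
        lo = np.maximum(sub["start"].to_numpy() - flank, 0)
        hi = sub["end"].to_numpy() + flank
        if np.any((lo <= p0) & (p0 < hi)):
            kept.append(a)
    return kept


def build_dataset(
    subjects: Sequence[SubjectRecord], endpoint: str = "by_cause"
) -> CompetingRisksDataset:
    """Construct the analysis dataset.

    ``endpoint='composite'`` codes any onset as event 1 (first clinical
    onset of either disease); ``'by_cause'`` codes AD as 1 and FTD as 2.
    Presymptomatic subjects are censored at the age of last follow-up.
    """
    if endpoint not in ("composite", "by_cause"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    time = np.array(
        [
            s.age_onset if s.diagnosis in ("AD", "FTD") else s.age_last_followup
            for s in subjects
        ],
        dtype=float,
    )
    if endpoint == "composite":
        event = np.array(
            [1 if s.diagnosis in ("AD", "FTD") else 0 for s in subjects], dtype=int
        )
    else:
        code = {"AD": 1, "FTD": 2, "presymptomatic": 0}
        event = np.array([code[s.diagnosis] for s in subjects], dtype=int)
    return CompetingRisksDataset(
        subject_id=np.array([s.subject_id for s in subjects]),
        time=time,
        event=event,
        cluster=np.array([s.family_id for s in subjects]),
    )
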