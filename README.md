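# burdencif

Competing-risks analysis of how a polygenic background of *non-causative*
variants modulates cumulative disease incidence in carriers of monogenic
Alzheimer's disease (AD) and frontotemporal dementia (FTD) mutations.

Carriers of causative variants in the AD genes (*APP*, *PSEN1*, *PSEN2*)
or FTD genes (*MAPT*, *GRN*, *C9orf72*) vary widely in age at onset.
This package implements an analysis of that variability for
biostatisticians and neurogenetics groups working with family-clustered
dementia cohorts: each subject contributes an age at onset (AD or FTD)
or a censored age at last follow-up, the two diseases are treated as
competing events, and per-subject **event-specific weighted burden
scores** summarize the subject's load of non-causative coding variants
in the same six genes.

## The model

For cause *k* (AD or FTD), each variant *j* gets a weight
β<sub>j</sub><sup>(k)</sup>: the coefficient of a univariate **Fine–Gray
subdistribution-hazard regression** of cause-*k* incidence on the
variant's dosage G<sub>ij</sub> ∈ {0,1,2}. A subject's score is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>i</sub><sup>(k)</sup> = Σ<sub>j</sub> G<sub>ij</sub> · β<sub>j</sub><sup>(k)</sup>

restricted to one gene set, giving four scores (AD- or FTD-gene variants,
AD- or FTD-risk weights). Non-estimable weights (e.g. a genotype absent
among subjects failing from that cause) are conservatively set to zero,
and variants in strong LD (pairwise r² ≥ 0.8 within one gene) are first
collapsed into an unweighted dosage-sum pseudo-variant.

The standardized AD-gene score *x* and FTD-gene score *z* (centered at
the mean, scaled by the P80 − P20 spread so one unit compares the 80th
vs 20th percentile) then enter Fine–Gray models under eight
specifications — null, x, z, x+z, x·z, x+x·z, z+x·z, x+z+x·z — per event
scenario, selected by AIC with family-cluster–robust (sandwich)
inference. A negative x:z coefficient in the AD scenario is the
gene–gene interaction signature of interest: a combined AD+FTD burden
raising AD incidence less than the product of the individual effects
(antagonistic pleiotropy). Supporting estimators: Kaplan–Meier and the
k-sample log-rank test for the composite any-dementia endpoint,
Aalen–Johansen cumulative incidence functions (CIFs), and **Gray's
k-sample test** comparing CIFs between score strata. A 5-fold
diagnosis-stratified cross-validation recomputes the scores out-of-fold,
and a sensitivity analysis re-estimates everything without *APOE* ε4
carriers.

No real cohort ships with the package: `burdencif.synthetic_data`
generates family-clustered cohorts with the study's shape (426 subjects,
64 non-causative variants split 3/7/12/22/16/4 across the six genes, a
six-variant PSEN1 LD block) under a law whose cause-1 subdistribution
hazard is exactly proportional, so every estimator is testable against
known truth.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/04_interaction_models.py
```

prints (cohort seed 20260926):

```
AD_event: selected M8 (argmin AIC (1118.53))
model  terms         aic  converged  selected
   M8 x+z+xz 1118.533802       True      True
   M4    x+z 1118.946196       True     False
   ...
  M8 x: sHR=2.55 (1.88-3.45) p=0.0000
  M8 z: sHR=3.60 (2.47-5.26) p=0.0000
  M8 xz: sHR=0.64 (0.40-1.01) p=0.0551
```

Read: with the FTD score at its mean, a subject at the 80th percentile
of the AD-gene score has a 2.55-fold higher subdistribution hazard of AD
onset than one at the 20th percentile (accounting for competing FTD
onset and family clustering); the x:z estimate below 1 means the joint
burden raises AD incidence less than multiplicatively. The remaining
drivers (`02` survival overview, `03` scores and Gray's tests, `05`
cross-validation, `06` APOE ε4 sensitivity) write their tables under
`results/`.

The same pipeline runs on real data from four files — a phenotype CSV, a
subjects×variants dosage TSV or VCF, a variant annotation table and a
BED of gene regions (±5 kb flanks are applied internally):

```
burdencif run-all --phenotypes P.csv --genotypes G.tsv \
    --annotations A.csv --regions R.bed --cv-seed 1 --out report/
```

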