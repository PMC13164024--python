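"""End-to-end analysis pipeline.

load -> survival overview (KM, log-rank, CIFs) -> LD blocks -> weights ->
scores (raw + cross-validated) -> interaction model grids -> APOE e4
sensitivity -> report bundle.  Numeric CSV/JSON outputs are the contract;
figures are optional artifacts behind a flag.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .burden_scores import (
    SCORE_NAMES,
    collapse_blocks,
    compute_scores,
    dichotomize,
    estimate_weights,
    ld_blocks,
    standardize_iqr,
)
from .competing_risks import cif_aalen_johansen, kaplan_meier, logrank_test
from .cross_validation import cv_scores, make_folds
from .interaction_analysis import (
    apoe_sensitivity,
    fit_model_grid,
    stratified_cif_analysis,
)
from .io_cohort import (
    build_dataset,
    filter_region_variants,
    read_annotations,
    read_genotypes,
    read_phenotypes,
    read_regions,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["RunConfig", "run_pipeline", "cohort_summary"]


@dataclass
class RunConfig:
    phenotypes: str
    genotypes: str
    annotations: str
    regions: str
    output_dir: str
    r2_threshold: float = 0.8
    flank: int = 5000
    quantiles: tuple = (20.0, 80.0)
    cv: bool = True
    cv_folds: int = 5
    cv_seed: int = 0
    exclude_apoe: bool = True
    override_prefer_interaction: bool = False
    figures: bool = False

    def validate(self):
        for key in ("phenotypes", "genotypes", "annotations", "regions"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"{key} file not found: {p}")


def cohort_summary(subjects) -> pd.DataFrame:
    """Counts by diagnosis, genetic group and sex, with age means/SDs."""
    if not subjects:
        return pd.DataFrame(
            columns=["diagnosis", "n", "n_female", "mean_age_onset",
                     "sd_age_onset", "mean_age_followup", "sd_age_followup"]
        )
    df = pd.DataFrame(
        {
            "diagnosis": [s.diagnosis for s in subjects],
            "gene": [s.causative_gene for s in subjects],
            "sex": [s.sex for s in subjects],
            "age_onset": [np.nan if s.age_onset is None else s.age_onset
                          for s in subjects],
            "age_followup": [s.age_last_followup for s in subjects],
        }
    )
    rows = []
    for diag, sub in df.groupby("diagnosis"):
        rows.append(
            {
                "diagnosis": diag,
                "n": len(sub),
                "n_female": int((sub.sex == "F").sum()),
                "mean_age_onset": sub.age_onset.mean(),
                "sd_age_onset": sub.age_onset.std(),
                "mean_age_followup": sub.age_followup.mean(),
                "sd_age_followup": sub.age_followup.std(),
            }
        )
    rows.append(
        {
            "diagnosis": "total",
            "n": len(df),
            "n_female": int((df.sex == "F").sum()),
            "mean_age_onset": df.age_onset.mean(),
            "sd_age_onset": df.age_onset.std(),
            "mean_age_followup": df.age_followup.mean(),
            "sd_age_followup": df.age_followup.std(),
        }
    )
    return pd.DataFrame(rows)


def _grid_to_json(grid):
    out = {"scenario": grid.scenario, "selected": grid.selected,
           "selection_note": grid.selection_note, "models": {}}
    for mid, fit in grid.fits.items():
        if fit is None:
            out["models"][mid] = {"aic": -2.0 * grid.null_loglik, "terms": {}}
            continue
        ci = fit.ci95
        out["models"][mid] = {
            "aic": None if not np.isfinite(fit.aic) else fit.aic,
            "converged": bool(fit.converged),
            "terms": {
                t: {
                    "coef": _f(fit.coef[i]),
                    "hr": _f(np.exp(fit.coef[i])),
                    "ci_low": _f(ci[i, 0]),
                    "ci_high": _f(ci[i, 1]),
                    "se_robust": _f(fit.se_robust[i]),
                    "p": _f(fit.wald_p[i]),
                    "estimable": bool(fit.estimable[i]),
                }
                for i, t in enumerate(fit.terms)
            },
        }
    return out


def _f(v):
    v = float(v)
    return None if not np.isfinite(v) else v


def _cif_tidy(cifs) -> pd.DataFrame:
    rows = []
    for key, est in cifs.items():
        score, stratum, cause = key
        for t, v in zip(est.jump_times, est.cif_values):
            rows.append({"score": score, "stratum": stratum, "cause": cause,
                         "time": t, "cif": v})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the JSON-ready summary dict.

    Writes, under ``config.output_dir``: the echoed config, cohort
    summary, KM/log-rank results, weight and score tables, CIF strata,
    Gray's tests, both model grids (raw and, if enabled, cross-validated
    scores), the APOE sensitivity grids, and ``summary.json`` holding all
    HRs/CIs/p-values/AICs.
    """
    t0 = _time.time()
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2))
    summary: dict = {"schema_version": SCHEMA_VERSION,
                     "package_version": __version__}

    def stage(name):
        logger.info("stage %-22s t=%.1fs", name, _time.time() - t0)

    # ---- load ----------------------------------------------------------
    stage("load")
    subjects = read_phenotypes(config.phenotypes)
    annotations = read_annotations(config.annotations)
    regions = read_regions(config.regions)
    G_all = read_genotypes(config.genotypes,
                           subjects=[s.subject_id for s in subjects])
    # align genotype rows to the phenotype order
    order = {s: i for i, s in enumerate(G_all.subjects)}
    missing_geno = [s.subject_id for s in subjects if s.subject_id not in order]
    if missing_geno:
        raise ValueError(f"subjects without genotypes: {missing_geno[:5]}")
    idx = [order[s.subject_id] for s in subjects]
    G_all.dosage = G_all.dosage[idx]
    G_all.missing = G_all.missing[idx]
    G_all.subjects = [s.subject_id for s in subjects]

    summary["cohort"] = {
        "n_subjects": len(subjects),
        "n_affected": sum(s.diagnosis != "presymptomatic" for s in subjects),
        "n_presymptomatic": sum(s.diagnosis == "presymptomatic" for s in subjects),
        "n_AD": sum(s.diagnosis == "AD" for s in subjects),
        "n_FTD": sum(s.diagnosis == "FTD" for s in subjects),
    }
    cohort_summary(subjects).to_csv(outdir / "cohort_summary.csv", index=False)

    # ---- region filter and non-causative restriction -------------------
    stage("variants")
    in_region = filter_region_variants(annotations, regions, flank=config.flank)
    non_causative = [a for a in in_region if a.variant_class == "non_causative"]
    keep_ids = [a.variant_id for a in non_causative if a.variant_id in G_all.variants]
    G = G_all.subset_variants(keep_ids)
    summary["variants"] = {
        "n_annotated": len(annotations),
        "n_in_region": len(in_region),
        "n_non_causative": len(non_causative),
        "per_gene": {
            g: sum(a.gene == g for a in non_causative)
            for g in sorted({a.gene for a in non_causative})
        },
    }

    # ---- survival overview ---------------------------------------------
    stage("survival")
    composite = build_dataset(subjects, "composite")
    by_cause = build_dataset(subjects, "by_cause")
    gene_groups = np.array([s.causative_gene for s in subjects])
    km = kaplan_meier(composite)
    lr_stat, lr_df, lr_p = logrank_test(composite, gene_groups)
    summary["composite_endpoint"] = {
        "logrank_statistic": lr_stat, "df": lr_df, "p": lr_p,
    }
    pd.DataFrame({"time": km.x, "survival": km.y}).to_csv(
        outdir / "km_composite.csv", index=False
    )
    overall = cif_aalen_johansen(by_cause)
    pd.concat(
        [
            pd.DataFrame({"time": est.jump_times, "cif": est.cif_values,
                          "cause": c})
            for c, est in overall.items()
        ]
    ).to_csv(outdir / "cif_overall.csv", index=False)

    # ---- LD, weights, scores -------------------------------------------
    stage("scores")
    ld = ld_blocks(G, non_causative, r2_threshold=config.r2_threshold)
    pd.DataFrame(ld.r2, index=ld.variants, columns=ld.variants).to_csv(
        outdir / "ld_r2.csv"
    )
    Gc, ann_c = collapse_blocks(G, ld, non_causative)
    weights = estimate_weights(Gc, by_cause, ann_c, cluster=by_cause.cluster)
    weights.table.to_csv(outdir / "weights.csv", index=False)
    scores = compute_scores(Gc, weights, ann_c)
    lo, hi = config.quantiles
    std = scores.standardized(lo, hi)
    dich = scores.dichotomized()
    score_table = scores.scores.copy()
    for c in SCORE_NAMES:
        score_table[f"{c}_std"] = std[c]
        score_table[f"{c}_high"] = dich[c]
    score_table.insert(0, "subject_id", scores.subjects)
    score_table.to_csv(outdir / "scores.csv", index=False)
    summary["ld"] = {"n_blocks": len(ld.blocks),
                     "block_sizes": [len(b) for b in ld.blocks]}
    affected_high_ad = dich.loc[by_cause.event == 1, "ad_w_ad"].mean()
    summary["scores"] = {
        "n_columns": len(Gc.variants),
        "frac_AD_subjects_high_AD_score": _f(affected_high_ad),
        "frac_FTD_subjects_high_FTD_score": _f(
            dich.loc[by_cause.event == 2, "ftd_w_ftd"].mean()
        ),
    }

    # ---- stratified CIFs + Gray ----------------------------------------
    stage("stratified CIFs")
    strat = pd.DataFrame({"ad_score": dich["ad_w_ad"], "ftd_score": dich["ftd_w_ftd"]})
    cifs, gray_df = stratified_cif_analysis(by_cause, strat)
    _cif_tidy(cifs).to_csv(outdir / "cif_strata.csv", index=False)
    gray_df.to_csv(outdir / "gray_tests.csv", index=False)
    summary["gray_tests"] = {
        f"{r.score}_cause{r.cause}": {"statistic": _f(r.statistic), "p": _f(r.p_value)}
        for r in gray_df.itertuples()
    }

    # ---- interaction grids (raw scores) --------------------------------
    stage("model grids")
    grids_raw = {
        "AD_event": fit_model_grid(
            by_cause, std["ad_w_ad"], std["ftd_w_ad"], scenario="AD_event",
            cluster=by_cause.cluster,
            override_prefer_interaction=config.override_prefer_interaction,
        ),
        "FTD_event": fit_model_grid(
            by_cause, std["ad_w_ftd"], std["ftd_w_ftd"], scenario="FTD_event",
            cluster=by_cause.cluster,
            override_prefer_interaction=config.override_prefer_interaction,
        ),
    }
    pd.concat([g.summary() for g in grids_raw.values()]).to_csv(
        outdir / "grid_raw.csv", index=False
    )
    summary["grids_raw"] = {k: _grid_to_json(g) for k, g in grids_raw.items()}

    # ---- cross-validated scores ----------------------------------------
    if config.cv:
        stage("cross-validation")
        diag = np.array([s.diagnosis for s in subjects])
        folds = make_folds(by_cause.subject_id, diag, k=config.cv_folds,
                           seed=config.cv_seed)
        cv, fold_log = cv_scores(Gc, by_cause, folds, ann_c,
                                 cluster=by_cause.cluster)
        fold_log.to_csv(outdir / "cv_folds.csv", index=False)
        cv_std = cv.standardized(lo, hi)
        cv_table = cv.scores.copy()
        cv_table.insert(0, "subject_id", cv.subjects)
        cv_table["fold"] = folds.fold
        cv_table.to_csv(outdir / "scores_cv.csv", index=False)
        grids_cv = {
            "AD_event": fit_model_grid(
                by_cause, cv_std["ad_w_ad"], cv_std["ftd_w_ad"],
                scenario="AD_event", cluster=by_cause.cluster,
                override_prefer_interaction=config.override_prefer_interaction,
            ),
            "FTD_event": fit_model_grid(
                by_cause, cv_std["ad_w_ftd"], cv_std["ftd_w_ftd"],
                scenario="FTD_event", cluster=by_cause.cluster,
                override_prefer_interaction=config.override_prefer_interaction,
            ),
        }
        pd.concat([g.summary() for g in grids_cv.values()]).to_csv(
            outdir / "grid_cv.csv", index=False
        )
        summary["grids_cv"] = {k: _grid_to_json(g) for k, g in grids_cv.items()}
        summary["cv"] = {"k": config.cv_folds, "seed": config.cv_seed}

    # ---- APOE sensitivity ----------------------------------------------
    if config.exclude_apoe:
        stage("APOE sensitivity")
        flags = [s.apoe_e4 for s in subjects]
        if any(v is None for v in flags):
            raise ValueError("APOE e4 flag unknown for some subjects; cannot "
                             "run the sensitivity analysis")
        sens, n_kept = apoe_sensitivity(
            by_cause, std["ad_w_ad"], std["ftd_w_ad"], std["ftd_w_ftd"],
            flags, x_ftd=std["ad_w_ftd"], cluster=by_cause.cluster,
            override_prefer_interaction=config.override_prefer_interaction,
        )
        pd.concat([g.summary() for g in sens.values()]).to_csv(
            outdir / "grid_apoe_sensitivity.csv", index=False
        )
        summary["apoe_sensitivity"] = {
            "n_analysed": n_kept,
            "n_excluded": len(subjects) - n_kept,
            "grids": {k: _grid_to_json(g) for k, g in sens.items()},
        }

    if config.figures:
        stage("figures")
        _make_figures(outdir, km, overall, cifs, ld)

    _validate_summary(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    stage("done")
    return summary


def _validate_summary(summary: dict) -> None:
    """Schema check before writing: required keys and JSON-serializability."""
    required = {"schema_version", "cohort", "variants", "gray_tests", "grids_raw"}
    missing = required - set(summary)
    if missing:
        raise ValueError(f"summary missing sections: {missing}")
    json.dumps(summary)  # raises on non-serializable content


def _make_figures(outdir, km, overall, cifs, ld):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.step(km.x, km.y, where="post")
    ax.set(xlabel="age (years)", ylabel="survival", title="Composite endpoint")
    fig.savefig(outdir / "km_composite.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for c, est in overall.items():
        ax.step(est.jump_times, est.cif_values, where="post",
                label=f"cause {c}")
    ax.set(xlabel="age (years)", ylabel="cumulative incidence")
    ax.legend()
    fig.savefig(outdir / "cif_overall.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    im = ax.imshow(ld.r2, vmin=0, vmax=1, cmap="Reds")
    fig.colorbar(im, ax=ax, label="r$^2$")
    ax.set_title("Pairwise LD")
    fig.savefig(outdir / "ld_heatmap.png", dpi=120)
    plt.close(fig)
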