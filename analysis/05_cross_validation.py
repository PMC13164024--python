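"""Out-of-fold burden scores and the interaction grids refitted on them.

Five diagnosis-stratified folds; each fold's subjects are scored with
weights estimated on the other four folds, the concatenated scores are
standardized once, and the eight-model grids are re-estimated.
"""

import numpy as np
import pandas as pd
from _common import CV_SEED, RESULTS, analysis_frames

from burdencif.cross_validation import cv_scores, make_folds
from burdencif.interaction_analysis import fit_model_grid


def main():
    subjects, data, Gc, ann_c, weights, scores = analysis_frames()
    diag = np.array([s.diagnosis for s in subjects])
    folds = make_folds(data.subject_id, diag, k=5, seed=CV_SEED)
    cv, fold_log = cv_scores(Gc, data, folds, ann_c, cluster=data.cluster)
    fold_log.to_csv(RESULTS / "cv_folds.csv", index=False)
    out = cv.scores.copy()
    out.insert(0, "subject_id", cv.subjects)
    out["fold"] = folds.fold
    out.to_csv(RESULTS / "scores_cv.csv", index=False)
    print(f"cross-validated scores for {len(out)} subjects "
          f"(fold seed {CV_SEED})")

    std = cv.standardized()
    grids = {
        "AD_event": fit_model_grid(data, std["ad_w_ad"], std["ftd_w_ad"],
                                   scenario="AD_event", cluster=data.cluster),
        "FTD_event": fit_model_grid(data, std["ad_w_ftd"], std["ftd_w_ftd"],
                                    scenario="FTD_event", cluster=data.cluster),
    }
    pd.concat(g.summary() for g in grids.values()).to_csv(
        RESULTS / "grid_cv.csv", index=False
    )
    for scen, g in grids.items():
        print(f"{scen} (CV scores): selected {g.selected} "
              f"({g.selection_note})")


if __name__ == "__main__":
    main()
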