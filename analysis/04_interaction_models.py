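"""The eight-model interaction grid for both event scenarios (raw scores).

x is the standardized AD-gene score and z the FTD-gene score, both
weighted by the scenario's cause; models are compared by AIC with
family-clustered robust inference.
"""

import pandas as pd
from _common import RESULTS, analysis_frames

from burdencif.interaction_analysis import fit_model_grid


def main():
    subjects, data, Gc, ann_c, weights, scores = analysis_frames()
    std = scores.standardized()

    grids = {
        "AD_event": fit_model_grid(data, std["ad_w_ad"], std["ftd_w_ad"],
                                   scenario="AD_event", cluster=data.cluster),
        "FTD_event": fit_model_grid(data, std["ad_w_ftd"], std["ftd_w_ftd"],
                                    scenario="FTD_event", cluster=data.cluster),
    }
    pd.concat(g.summary() for g in grids.values()).to_csv(
        RESULTS / "grid_raw.csv", index=False
    )
    for scen, g in grids.items():
        print(f"{scen}: selected {g.selected} ({g.selection_note})")
        print(g.aic_table().to_string(index=False))
        m8 = g.fits["M8"]
        for i, t in enumerate(m8.terms):
            lo, hi = m8.ci95[i]
            print(f"  M8 {t}: sHR={m8.hr[i]:.2f} ({lo:.2f}-{hi:.2f}) "
                  f"p={m8.wald_p[i]:.4f}")


if __name__ == "__main__":
    main()
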