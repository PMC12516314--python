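#!/usr/bin/env python
"""Predict individual outcomes from leave-one-out interference histograms.

For each subject the heatmap is rebuilt from the other n-1 subjects and
the subject's two VTAs are sampled on it; the 15-bin count histogram of
sampled signed-p values is the predictor vector. A multivariate OLS model
(improvement ~ bin counts) is fitted and cross-validated leave-one-out.
The simpler baselines — distance of active contacts to the sweetspot COG
and the stimulation parameters — are reported for comparison; both are
expected to explain far less variance than the histogram model.

Reads results/cohort/ and results/spots.json; writes
results/histograms.csv, results/predictions.csv and
results/prediction_metrics.json.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

import stimmap as sm
from stimmap.io import load_cohort, write_cohort_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
warnings.filterwarnings("ignore", message="dropping constant")

cohort = load_cohort(args.outdir / "cohort")
y = cohort.outcomes()

hists = sm.loo_histograms(cohort)
model = sm.fit_outcome_model(hists, y)
cv = sm.loocv_predict(hists, y)

spots = json.loads((args.outdir / "spots.json").read_text())
sweet_cog = next(s["cog"] for s in spots if s["sign"] > 0)
r2_cog, p_cog, slope = sm.cog_distance_regression(cohort, sweet_cog)
r2_par, p_par = sm.stimparams_regression(cohort)

write_cohort_table(
    pd.DataFrame(
        [{"subject_id": h.subject_id, "fold_id": h.fold_id,
          **{f"bin_{i:02d}": int(c) for i, c in enumerate(h.counts)}} for h in hists]
    ),
    args.outdir / "histograms.csv",
)
write_cohort_table(cv.to_frame(), args.outdir / "predictions.csv")
metrics = {
    "fit_r_squared": model.r_squared,
    "fit_f_pvalue": model.f_pvalue,
    "loocv_pearson_r": cv.pearson_r,
    "loocv_p_value": cv.p_value,
    "cog_distance_r_squared": r2_cog,
    "cog_distance_p": p_cog,
    "stimparams_r_squared": r2_par,
    "stimparams_p": p_par,
}
(args.outdir / "prediction_metrics.json").write_text(json.dumps(metrics, indent=1))

print(f"histogram model: R^2 = {model.r_squared:.2f} (F-test p = {model.f_pvalue:.2g})")
print(f"LOOCV: Pearson R = {cv.pearson_r:.2f} (p = {cv.p_value:.2g})")
print(f"baseline, COG distance:       R^2 = {r2_cog:.2f} (p = {p_cog:.2g})")
print(f"baseline, stim parameters:    R^2 = {r2_par:.2f} (p = {p_par:.2g})")
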