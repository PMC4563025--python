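#!/usr/bin/env python
"""Fit the model family to the synthetic cohort and compare fits.

Requires results/cohort/trials.csv (run 03_generate_cohort.py first). Fits
Rescorla-Wagner, Pearce-Hall, SD-specific-alpha PH, and the log-adaptive PH
with free nu to every participant; tabulates per-participant fits,
aggregated AIC differences, and likelihood-ratio tests for the nested pairs.

Finding: on a cohort generated from the log-adaptive model, the adaptive
model achieves the lowest aggregated AIC and the nested LR tests against
RW/PH are significant, mirroring the ordering of the reported comparison
table at synthetic-data scale.
"""

import pandas as pd

from pescale.fitting import FitConfig, compare_models
from pescale.io import read_trial_table, write_table

SEED = 0
MODELS = ["rw", "ph", "ph-sd", "aph-log"]

dataset = read_trial_table("results/cohort/trials.csv")
res = compare_models(dataset, MODELS, FitConfig(seed=SEED), criterion="aic")

write_table(res["fit_table"], "results/fits/per_participant_fits.csv", {"seed": SEED})
write_table(res["d_matrix"].reset_index(names="model"),
            "results/fits/aggregated_daic_matrix.csv", {"seed": SEED})

lrt_rows = [
    {"restricted": t.restricted, "full": t.full, "d_aic": round(t.d_aic, 2),
     "lr": round(t.lr, 2), "df": t.df, "p": t.p_value}
    for t in res["lr_tests"]
]
write_table(pd.DataFrame(lrt_rows), "results/fits/likelihood_ratio_tests.csv", {"seed": SEED})

print("aggregated AIC by model:")
for m, v in sorted(res["aggregated"].items(), key=lambda kv: kv[1]):
    print(f"  {m:8s} {v:10.1f}")
print("\nbest model per participant:")
print(res["best_counts"].to_string())
print("\nnested likelihood-ratio tests:")
for t in res["lr_tests"]:
    print(" ", t)
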