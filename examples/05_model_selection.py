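"""Leave-one-subject-out model comparison with random-effects BMS.

Simulates a small cohort whose ROI-mean signal is generated from the latent
structure modulator, scores all three models per held-out subject by
BIC -> log evidence, and pools the evidence with random-effects Bayesian
model selection (protected exceedance probabilities and Bayesian omnibus
risk).
"""

import numpy as np

from socstruct import selection

cohort = selection.simulate_roi_cohort(
    n_subjects=8, generator="latent", noise_sd=0.5, seed=42, n_runs=2
)
evidence, result = selection.loso_harness(cohort, n_samples=100_000, seed=0)

print("log evidence per fold (relative to each subject's best model):")
print(evidence.sub(evidence.max(axis=1), axis=0).round(2).to_string())
print("\nexpected model frequencies:",
      dict(zip(result.models, np.round(result.expected_freq, 3))))
print("protected exceedance probs:",
      dict(zip(result.models, np.round(result.protected_exceedance_prob, 4))))
print(f"Bayesian omnibus risk: {result.bor:.4f}")

# The generating (latent) model attains the highest PXP and the omnibus
# risk is low: the group analysis correctly concludes one model dominates.
# Feeding equal evidence instead drives PXP to 1/3 each and BOR toward 1.
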