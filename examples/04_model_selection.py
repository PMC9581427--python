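"""Random-effects Bayesian model selection on synthetic evidences.

Builds a cohort in which most subjects are best described by one model and
shows how the protected exceedance probability (PEP) identifies it while the
Bayes omnibus risk guards against spurious wins.
"""

import numpy as np

from tonedrift import rfx_bms

rng = np.random.default_rng(0)
n_subjects, models = 20, ["base", "bias_only", "full"]

# log evidences (e.g., -AIC/2): "full" better by ~3 units in 16/20 subjects
log_ev = rng.normal(0.0, 1.0, size=(n_subjects, 3))
log_ev[:16, 2] += 3.0

table = rfx_bms(log_ev, variants=models, seed=1)
for name, ef, pep in zip(models, table.expected_freq, table.pep):
    print(f"{name:10s} expected freq = {ef:.3f}  PEP = {pep:.3f}")
print(f"Bayes omnibus risk = {table.bor:.4f}")

# And a null cohort: exchangeable evidences should split PEP ~ uniformly.
null = rfx_bms(rng.normal(0.0, 1.0, size=(n_subjects, 3)),
               variants=models, seed=2)
print("null-cohort PEPs:", np.round(null.pep, 3))
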