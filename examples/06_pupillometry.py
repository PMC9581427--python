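"""Pupillometry pipeline on a synthetic rule-based cohort.

Generates eight subjects whose pupil transient is larger on prior-
incongruent choices, runs cleaning / epoching / exclusion, and tests the
incongruent-congruent contrast per 20-ms bin with FDR correction.
"""

import numpy as np
import pandas as pd

from tonedrift import (CohortSpec, SessionDesign, clean_trace, congruence_label,
                       epoch_and_exclude, generate_pupil, generate_session,
                       simulate_trials, table_means, timecourse_contrasts)

spec = CohortSpec(n_subjects=8, conditions=("rule",), pupil_effect=0.3, seed=0)
rng = np.random.default_rng(spec.seed)
params = table_means("rule")

rows, mats = [], []
for s in range(spec.n_subjects):
    sid = f"S{s:02d}"
    sess = generate_session(SessionDesign.default("rule", n_trials=144),
                            rng, sid)
    done = [t for t in simulate_trials(params, sess, rng)
            if t.choice != "none"]
    rec = clean_trace(generate_pupil(done, spec, rng))
    epochs, report = epoch_and_exclude(rec, sid)
    binned = epochs.downsampled()
    for i, t in enumerate(done):
        lab = congruence_label(t)
        if epochs.excluded[i] or lab not in ("congruent", "incongruent"):
            continue
        rows.append(dict(subject=sid,
                         congr=0.5 if lab == "incongruent" else -0.5,
                         tone=0.5 if t.tone == "H" else -0.5,
                         abssnr=abs(t.snr_unit),
                         baseline=epochs.baselines[i]))
        mats.append(binned[i])
print(f"{len(rows)} analyzable trials from {spec.n_subjects} subjects")

res = timecourse_contrasts(pd.DataFrame(rows), np.array(mats), ["congr"],
                           ["tone", "abssnr", "baseline"],
                           epochs.bin_times_ms)
sig = res[res.significant]
print(f"significant incongruent-congruent bins: {len(sig)} / {len(res)}")
if len(sig):
    print(f"  window {sig.bin_ms.min():.0f}..{sig.bin_ms.max():.0f} ms "
          f"post-choice, peak beta = {sig.beta.max():.3f} z-units")

# The injected 0.3 z-unit transient should surface as a cluster of
# significant positive bins a few hundred ms after the choice, mirroring a
# congruence-dependent arousal response.
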