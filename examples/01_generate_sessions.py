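"""Generate task sessions and inspect their structure.

Builds one rule-based session (576 trials, twelve 48-trial mini-blocks with a
constant prior cue each) and one stimulus-based session (480 trials, 38 of
which lack a pre-test tone sequence and are dropped before analysis), then
prints the headline counts and the dB -> unit SNR mapping.
"""

import numpy as np

from tonedrift import (SessionDesign, filter_analyzable, generate_session,
                       map_snr, task_design)

rng = np.random.default_rng(0)

rule = generate_session(SessionDesign.default("rule"), rng, subject_id="S00")
stim = generate_session(SessionDesign.default("stim"), rng, subject_id="S00")

print(f"rule session: {len(rule)} trials, "
      f"{len({t.block for t in rule})} mini-blocks")
print(f"stim session: {len(stim)} trials, "
      f"{len(filter_analyzable(stim))} analyzable after no-pretest exclusion")
for db in task_design.SNR_DB_LEVELS:
    print(f"  {db:6.1f} dB -> unit SNR {map_snr(db, 'H'):+.4f} (high tone)")

# Each printed unit SNR is the signed stimulus-strength value the models use:
# the sign encodes tone identity, the magnitude rescales dB onto [0.05, 0.5].
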