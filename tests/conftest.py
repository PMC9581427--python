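import dataclasses

import numpy as np
import pytest

import tonedrift as td


def make_trial(tone="H", snr_db=-6.0, session_type="rule", cue="neutral",
               pretest=(), choice="none", rt=float("nan"), window=2.0,
               trial_index=0):
    """Convenience constructor for a single consistent trial."""
    snr_unit = td.map_snr(snr_db, tone)
    return td.Trial(
        subject_id="T00", session_type=session_type, trial_index=trial_index,
        tone=tone, snr_db=snr_db, snr_unit=snr_unit,
        cue=td.task_design.CUES[cue] if cue else None,
        pretest=tuple(pretest), choice=choice, rt=rt,
        correct=(choice == tone), response_window=window,
    )


@pytest.fixture(scope="session")
def rule_means():
    return td.table_means("rule")


@pytest.fixture(scope="session")
def stim_means():
    return td.table_means("stim")


@pytest.fixture(scope="session")
def rule_session_sim(rule_means):
    """One simulated rule-based session at the published mean parameters."""
    rng = np.random.default_rng(123)
    sess = td.generate_session(td.SessionDesign.default("rule"), rng, "S00")
    done = td.simulate_trials(rule_means, sess, rng)
    return [t for t in done if t.choice != "none"]


@pytest.fixture(scope="session")
def stim_session_sim(stim_means):
    """One simulated stimulus-based session at the published means."""
    rng = np.random.default_rng(456)
    sess = td.filter_analyzable(
        td.generate_session(td.SessionDesign.default("stim"), rng, "S00"))
    done = td.simulate_trials(stim_means, sess, rng)
    return [t for t in done if t.choice != "none"]
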