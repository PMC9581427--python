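import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tonedrift as td
from tonedrift.task_design import (SNR_DB_LEVELS, SessionDesign, CUES,
                                   frame_to_trials, sample_pretest_sequence,
                                   trials_to_frame)


class TestMapSnr:
    @pytest.mark.parametrize("db,tone,expected", [
        (-23.0, "H", 0.05),
        (-6.0, "L", -0.5),
        (-18.0, "H", 0.05 + (5 / 17) * 0.45),
    ])
    def test_endpoint_and_interior_values(self, db, tone, expected):
        assert td.map_snr(db, tone) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            td.map_snr(-30.0, "H")
        with pytest.raises(ValueError):
            td.map_snr(0.0, "L")

    @given(st.floats(min_value=-23.0, max_value=-6.0),
           st.floats(min_value=-23.0, max_value=-6.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_odd(self, a, b):
        if a < b:
            assert td.map_snr(a, "H") < td.map_snr(b, "H")
        assert td.map_snr(a, "H") == pytest.approx(-td.map_snr(a, "L"))


class TestPretestSequences:
    def test_lengths_within_bounds(self):
        rng = np.random.default_rng(0)
        lens = {len(sample_pretest_sequence(rng)) for _ in range(500)}
        assert min(lens) >= 2 and max(lens) <= 14

    def test_degenerate_fixed_length(self):
        rng = np.random.default_rng(1)
        assert all(len(sample_pretest_sequence(rng, 5, 5)) == 5
                   for _ in range(50))

    def test_tone_identity_balanced(self):
        rng = np.random.default_rng(2)
        tones = [t for _ in range(10_000)
                 for t in sample_pretest_sequence(rng)]
        freq_h = sum(t == "H" for t in tones) / len(tones)
        assert freq_h == pytest.approx(0.5, abs=0.02)


class TestGenerateSession:
    def test_rule_session_structure(self):
        rng = np.random.default_rng(3)
        sess = td.generate_session(SessionDesign.default("rule"), rng)
        assert len(sess) == 576
        blocks = {}
        for t in sess:
            blocks.setdefault(t.block, set()).add(t.cue.label)
        assert len(blocks) == 12
        assert all(len(c) == 1 for c in blocks.values())  # constant-cue blocks
        # counterbalanced: each cue label heads four mini-blocks
        labels = [next(iter(c)) for c in blocks.values()]
        assert sorted(labels.count(c) for c in ("low", "neutral", "high")) == [4, 4, 4]

    def test_stim_session_counts(self):
        rng = np.random.default_rng(4)
        sess = td.generate_session(SessionDesign.default("stim"), rng)
        assert len(sess) == 480
        assert len(td.filter_analyzable(sess)) == 442

    def test_reproducible_given_seed(self):
        a = td.generate_session(SessionDesign.default("stim"),
                                np.random.default_rng(7))
        b = td.generate_session(SessionDesign.default("stim"),
                                np.random.default_rng(7))
        assert a == b

    def test_tone_frequency_tracks_cue(self):
        rng = np.random.default_rng(8)
        counts = {c: [0, 0] for c in CUES}
        for _ in range(8):
            for t in td.generate_session(SessionDesign.default("rule"), rng):
                counts[t.cue.label][0] += t.tone == "H"
                counts[t.cue.label][1] += 1
        for label, (h, n) in counts.items():
            p = CUES[label].p_high
            se = (p * (1 - p) / n) ** 0.5
            assert abs(h / n - p) < 3 * se + 1e-9

    def test_mixed2_fixed_length_pretests(self):
        rng = np.random.default_rng(9)
        sess = td.generate_session(SessionDesign.default("mixed2"), rng)
        assert len(sess) == 576
        assert all(len(t.pretest) == 5 for t in sess)
        assert all(t.cue is not None for t in sess)


class TestFilterAnalyzable:
    def test_rule_trials_unchanged(self):
        rng = np.random.default_rng(10)
        sess = td.generate_session(SessionDesign.default("rule"), rng)
        assert td.filter_analyzable(sess) == sess

    def test_empty_input(self):
        assert td.filter_analyzable([]) == []

    def test_order_preserved(self):
        rng = np.random.default_rng(11)
        sess = td.generate_session(SessionDesign.default("stim"), rng)
        kept = td.filter_analyzable(sess)
        idx = [t.trial_index for t in kept]
        assert idx == sorted(idx)


def test_trial_table_round_trip(tmp_path, rule_session_sim):
    path = tmp_path / "trials.csv"
    td.write_trials(rule_session_sim[:100], path)
    back = td.read_trials(path)
    for a, b in zip(rule_session_sim[:100], back):
        assert a.choice == b.choice and a.pretest == b.pretest
        assert a.cue == b.cue and a.tone == b.tone
        assert a.rt == pytest.approx(b.rt, rel=1e-6)


def test_trial_validation_rules():
    with pytest.raises(ValueError):
        td.Trial(subject_id="x", session_type="rule", trial_index=0,
                 tone="H", snr_db=-6.0, snr_unit=-0.5)  # sign mismatch
    with pytest.raises(ValueError):
        td.Trial(subject_id="x", session_type="rule", trial_index=0,
                 tone="H", snr_db=-6.0, snr_unit=0.5, choice="H", rt=2.5)
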