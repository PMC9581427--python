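import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import tonedrift as td
from tonedrift.pupil import (PupilRecording, bias_pupil_correlation,
                             clean_trace, epoch_and_exclude,
                             timecourse_contrasts)


def _recording(n=20_000, diameter=None, missing=None, gaze=None,
               events=None, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    if diameter is None:
        diameter = 3000 + rng.normal(0, 1.0, n)
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    gx = gaze if gaze is not None else rng.normal(0, 0.3, n)
    if events is None:
        events = pd.DataFrame({"trial_index": [0],
                               "tone_onset_ms": [5000],
                               "choice_ms": [5600]})
    return PupilRecording(t_ms=t, diameter=diameter, gaze_x=gx,
                          gaze_y=rng.normal(0, 0.3, n),
                          missing_mask=missing, events=events)


class TestCleanTrace:
    def test_artifact_free_trace_not_interpolated(self):
        cl = clean_trace(_recording())
        assert not cl.interp_mask.any()

    def test_blink_guard_band(self):
        missing = np.zeros(20_000, dtype=bool)
        missing[1000:1051] = True
        cl = clean_trace(_recording(missing=missing))
        assert cl.interp_mask[900:1151].all()
        assert not cl.interp_mask[899] and not cl.interp_mask[1151]

    def test_short_velocity_run_no_expansion(self):
        diam = 3000 * np.ones(20_000)
        diam[2000:2010] += np.arange(10) * 50.0  # 50 a.u./ms for 10 ms
        cl = clean_trace(_recording(diameter=diam))
        span = np.where(cl.interp_mask)[0]
        assert span.size > 0
        assert span.min() >= 1995 and span.max() <= 2015

    def test_long_velocity_run_expanded(self):
        diam = 3000 * np.ones(20_000)
        diam[2000:2040] += np.arange(40) * 50.0  # 40 ms excursion
        cl = clean_trace(_recording(diameter=diam))
        assert cl.interp_mask[1910:2130].all()

    def test_idempotent(self):
        missing = np.zeros(20_000, dtype=bool)
        missing[3000:3100] = True
        once = clean_trace(_recording(missing=missing))
        twice = clean_trace(once)
        np.testing.assert_array_equal(once.diameter, twice.diameter)

    def test_filter_attenuation(self):
        t = np.arange(20_000) / 1000.0
        for freq, db_lo, db_hi in ((20.0, 20.0, np.inf), (1.0, -1.0, 1.0)):
            diam = 3000 + 100 * np.sin(2 * np.pi * freq * t)
            cl = clean_trace(_recording(diameter=diam))
            amp = (cl.diameter[5000:15000].max()
                   - cl.diameter[5000:15000].min()) / 2
            atten_db = -20 * np.log10(amp / 100)
            assert atten_db >= db_lo
            if np.isfinite(db_hi):
                assert atten_db <= db_hi


class TestEpochAndExclude:
    def test_baseline_window_zeroed(self):
        cl = clean_trace(_recording(seed=3))
        ep, _ = epoch_and_exclude(cl, epoch_ms=(-700, 1300))
        # re-check against the recording: mean of 0-40 ms post onset == base
        assert ep.traces.shape[0] == 1
        onset, choice = 5000, 5600
        rel = onset - (choice + ep.times_ms[0])
        assert rel >= 0
        seg = ep.traces[0, rel:rel + 40]
        assert np.nanmean(seg) == pytest.approx(0.0, abs=1e-9)

    def test_missing_data_exclusion(self):
        missing = np.zeros(20_000, dtype=bool)
        missing[5100:6700] = True  # most of the epoch window interpolated
        cl = clean_trace(_recording(missing=missing))
        ep, report = epoch_and_exclude(cl)
        assert report["n_missing_data"] == 1
        assert ep.exclusion_reason[0] == "missing_data"

    def test_gaze_excursion_exclusion(self):
        gaze = np.random.default_rng(0).normal(0, 0.2, 20_000)
        gaze[5800:5830] = 8.0  # 30 ms far outside any fixation circle
        cl = clean_trace(_recording(gaze=gaze))
        ep, report = epoch_and_exclude(cl, fixation_radius=2.0)
        assert report["n_gaze"] == 1

    def test_zero_variance_block_flagged(self):
        cl = clean_trace(_recording(diameter=np.full(20_000, 2500.0)))
        ep, _ = epoch_and_exclude(cl)
        assert ep.zero_variance_flag
        assert np.nanmax(np.abs(ep.traces)) == 0.0

    def test_downsample_shape(self):
        cl = clean_trace(_recording())
        ep, _ = epoch_and_exclude(cl, epoch_ms=(-500, 1500))
        assert ep.downsampled().shape == (1, 100)
        assert ep.bin_times_ms[0] == pytest.approx(-490.5)

    def test_unfiltered_recording_rejected(self):
        with pytest.raises(ValueError):
            epoch_and_exclude(_recording())


class TestGroupStatistics:
    def test_bh_step_up_hand_example(self):
        p = np.array([0.005, 0.02, 0.03, 0.05])
        _, adj, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.05])

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(1)
        n_sub, n_tr, n_bins = 10, 60, 40
        bins = np.arange(n_bins) * 20.0
        effect_bins = (bins >= 200) & (bins <= 800)
        rows, mats = [], []
        for s in range(n_sub):
            congr = rng.choice([-0.5, 0.5], n_tr)
            x = rng.normal(0, 0.5, (n_tr, n_bins))
            x[:, effect_bins] += 0.3 * congr[:, None]
            rows.append(pd.DataFrame({"subject": f"S{s}", "congr": congr,
                                      "cov": rng.normal(size=n_tr)}))
            mats.append(x)
        res = timecourse_contrasts(pd.concat(rows, ignore_index=True),
                                   np.vstack(mats), ["congr"], ["cov"], bins)
        sig = res[res.significant]
        assert len(sig) > 0
        assert sig.bin_ms.min() >= 200 and sig.bin_ms.max() <= 800
        assert (sig.beta > 0).all()

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"subject": ["A"] * 40 + ["B"] * 40,
                           "congr": rng.choice([-0.5, 0.5], 80)})
        df["dup"] = df["congr"]  # perfectly collinear with the contrast
        mats = rng.normal(size=(80, 10))
        res = timecourse_contrasts(df, mats, ["congr"], ["dup"])
        assert np.isfinite(res["beta"]).all()

    def test_bias_pupil_correlation_monotone(self):
        bias = np.linspace(0, 2, 12)
        betas = np.tile(bias[:, None] ** 2, (1, 5))
        out = bias_pupil_correlation(bias, betas)
        assert np.allclose(out["rho"], 1.0)

    def test_bias_pupil_correlation_needs_ten(self):
        with pytest.raises(ValueError):
            bias_pupil_correlation(np.arange(5.0), np.zeros((5, 3)))
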