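import dataclasses
import math

import numpy as np
import pytest

import tonedrift as td
from tonedrift.psychometrics import (LogisticFit, bias_coupling, choice_bias,
                                     chronometric_summary, congruence_label,
                                     fit_logistic, predict_choice_prob)

from conftest import make_trial


def _bias_fit(lapse=0.0, beta_snr=8.0, b0=(0.0, 0.0, 0.0)):
    return LogisticFit(model="bias", lapse=lapse, beta_snr=beta_snr,
                       beta0_by_cue=dict(zip(("low", "neutral", "high"), b0)))


class TestPredictChoiceProb:
    def test_neutral_midpoint(self):
        fit = _bias_fit(beta_snr=0.0)
        assert predict_choice_prob(fit, make_trial()) == pytest.approx(0.5)

    def test_lapse_asymptote(self):
        fit = _bias_fit(lapse=0.02, beta_snr=1e4)
        p = predict_choice_prob(fit, make_trial(tone="H", snr_db=-6.0))
        assert p == pytest.approx(0.98, abs=1e-6)

    def test_stim_position_contrast_code(self):
        fit = LogisticFit(model="stim_bias", lapse=0.0, beta_snr=0.0,
                          beta0=0.0, beta_pt=np.array([0.8, 0.0]), n_back=2)
        t = make_trial(session_type="stim", cue=None, pretest=("L", "H"))
        assert predict_choice_prob(fit, t) == pytest.approx(
            1 / (1 + math.exp(-0.4)))

    def test_monotone_in_snr(self):
        fit = _bias_fit(lapse=0.1, beta_snr=5.0)
        ps = [predict_choice_prob(fit, make_trial(tone=tone, snr_db=db))
              for tone, db in (("L", -6.0), ("L", -18.0), ("H", -18.0),
                               ("H", -6.0))]
        assert np.all(np.diff(ps) > 0)

    def test_sign_equivariance(self):
        fit = LogisticFit(model="stim_bias", lapse=0.03, beta_snr=6.0,
                          beta0=0.0, beta_pt=np.array([0.7, 0.3]), n_back=2)
        t = make_trial(session_type="stim", cue=None, pretest=("L", "H"),
                       tone="H", snr_db=-13.0)
        flipped = make_trial(session_type="stim", cue=None,
                             pretest=("H", "L"), tone="L", snr_db=-13.0)
        assert predict_choice_prob(fit, t) == pytest.approx(
            1 - predict_choice_prob(fit, flipped))


@pytest.fixture(scope="module")
def bias_cohort():
    """5,000 trials from a known rule-based bias model."""
    rng = np.random.default_rng(12)
    trials = []
    while len(trials) < 5000:
        sess = td.generate_session(td.SessionDesign.default("rule"),
                                   rng, "S00")
        for t in sess:
            f = {"low": -1.0, "neutral": 0.0, "high": 1.0}[t.cue.label] \
                + 10.0 * t.snr_unit
            p = 0.02 + 0.96 / (1 + np.exp(-f))
            ch = "H" if rng.random() < p else "L"
            trials.append(dataclasses.replace(
                t, choice=ch, rt=0.5, correct=(ch == t.tone)))
    return trials[:5000]


class TestFitLogistic:
    def test_parameter_counts(self, bias_cohort):
        stim = [make_trial(session_type="stim", cue=None,
                           pretest=("H", "L"), choice="H", rt=0.5,
                           trial_index=i) for i in range(60)]
        assert fit_logistic(bias_cohort[:200], "base").n_params == 3
        assert fit_logistic(bias_cohort[:200], "bias").n_params == 5
        assert fit_logistic(bias_cohort[:200], "bias_sensitivity").n_params == 7
        assert fit_logistic(stim, "stim_bias", n_back=2).n_params == 5
        assert fit_logistic(stim, "stim_bias_adapt", n_back=2).n_params == 7

    def test_recovery_within_fifteen_percent(self, bias_cohort):
        fit = fit_logistic(bias_cohort, "bias", seed=1)
        assert fit.beta_snr == pytest.approx(10.0, rel=0.15)
        assert fit.beta0_by_cue["high"] == pytest.approx(1.0, rel=0.15)
        assert fit.beta0_by_cue["low"] == pytest.approx(-1.0, rel=0.15)
        assert choice_bias(fit) == pytest.approx(2.0, rel=0.15)

    def test_nested_loglik_ordering(self, stim_session_sim):
        lls = [fit_logistic(stim_session_sim, m, n_back=2, seed=0).loglik
               for m in ("base", "stim_bias", "stim_bias_adapt")]
        assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([make_trial(choice="H", rt=0.5)] * 10, "base")


class TestChronometricSummary:
    def test_constant_rts(self):
        trials = [make_trial(cue="high", tone="H", choice="H", rt=0.4,
                             trial_index=i) for i in range(20)]
        out = chronometric_summary(trials)
        assert set(out["median_rt_s"]) == {0.4}

    def test_odd_count_median(self):
        rts = [0.3, 0.4, 1.0]
        trials = [make_trial(cue="high", tone="H", choice="H", rt=r,
                             trial_index=i) for i, r in enumerate(rts)]
        out = chronometric_summary(trials)
        assert out["median_rt_s"].iloc[0] == pytest.approx(0.4)

    def test_congruence_labels(self):
        assert congruence_label(make_trial(cue="high", choice="H", rt=.5)) == \
            "congruent"
        assert congruence_label(make_trial(cue="low", choice="H", rt=.5)) == \
            "incongruent"
        assert congruence_label(make_trial(cue="neutral", choice="H",
                                           rt=.5)) == "neutral"
        t = make_trial(session_type="stim", cue=None, pretest=("H", "H"),
                       choice="H", rt=.5)
        assert congruence_label(t) == "congruent"
        t2 = make_trial(session_type="stim", cue=None, pretest=("L", "H"),
                        choice="H", rt=.5)
        assert congruence_label(t2) is None


class TestBiasCoupling:
    def test_perfectly_anti_monotone(self):
        z = np.linspace(-1, 1, 15)
        s = bias_coupling(z, -z**3)
        assert s.coupling_rho == pytest.approx(-1.0)

    def test_null_distribution(self):
        # |rho| >= 0.29 is the ~5% two-sided critical region at n = 45; the
        # empirical exceedance rate must match it up to binomial MC error
        rng = np.random.default_rng(0)
        big = 0
        n_sim = 1000
        for _ in range(n_sim):
            s = bias_coupling(rng.normal(size=45), rng.normal(size=45))
            big += abs(s.coupling_rho) >= 0.29
        assert big / n_sim <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_constant_vector_flagged(self):
        s = bias_coupling(np.zeros(12), np.arange(12.0))
        assert s.flagged and math.isnan(s.coupling_rho)

    def test_generator_coupling_recovered(self):
        spec = td.CohortSpec(coupling=-0.6)
        rng = np.random.default_rng(99)
        zs, vs = [], []
        for _ in range(200):
            p = td.sample_subject_params(spec, rng, "rule")
            zs.append(p.z_high)
            vs.append(p.v_high)
        s = bias_coupling(zs, vs)
        assert s.coupling_rho == pytest.approx(-0.6, abs=0.15)
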