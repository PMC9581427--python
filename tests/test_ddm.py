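import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tonedrift as td
from tonedrift.ddm import TrialDrivers, solve_fpt
from tonedrift._kernels import simulate_paths_core

from conftest import make_trial


def closed_form_p_upper(mu, B, start_frac):
    """Absorption probability at the upper of two fixed bounds, sigma = 1."""
    a = start_frac * 2 * B
    if mu == 0:
        return a / (2 * B)
    return (1 - math.exp(-2 * mu * a)) / (1 - math.exp(-2 * mu * 2 * B))


class TestHistoryTerms:
    @pytest.mark.parametrize("seq,tau,expected", [
        ((), 1.0, 0.0),
        (("H",), 3.0, 1.0),
        (("L", "H"), 1.0, 1.0 - math.exp(-1)),  # H at position 0, L at 1
    ])
    def test_pt_bias_values(self, seq, tau, expected):
        assert td.compute_pt_bias(seq, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,vh,vl,tau,expected", [
        ((), -1.0, -2.0, 1.0, 0.0),
        (("H",), -1.40, -2.31, 1 / 7.04, -1.40),
        (("H", "H"), -1.0, 0.0, 1.0, -(1 + math.exp(-1))),
    ])
    def test_adapt_values(self, seq, vh, vl, tau, expected):
        assert td.compute_adapt(seq, vh, vl, tau) == pytest.approx(expected)

    @given(st.lists(st.sampled_from("LH"), max_size=14),
           st.floats(min_value=0.05, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_pt_bias_antisymmetric_under_label_swap(self, seq, tau):
        swapped = ["H" if t == "L" else "L" for t in seq]
        assert td.compute_pt_bias(seq, tau) == pytest.approx(
            -td.compute_pt_bias(swapped, tau))


class TestTrialDrivers:
    def test_rule_high_cue_drift(self, rule_means):
        t = make_trial(tone="H", snr_db=-6.0, cue="high")
        d = td.trial_drivers(rule_means, t)
        assert d.drift == pytest.approx(6.51 * 0.5 + 0.67)

    def test_stim_unbiased_limit(self):
        p = td.DDMParams(v_snr=4.0)
        t = make_trial(session_type="stim", cue=None, pretest=("L", "H"))
        d = td.trial_drivers(p, t)
        assert d.drift == pytest.approx(4.0 * 0.5)
        assert d.start_frac == pytest.approx(0.5)

    def test_stim_full_composition(self, stim_means):
        t = make_trial(session_type="stim", cue=None, pretest=("H", "H"))
        d = td.trial_drivers(stim_means, t)
        pt = 1 + math.exp(-1 / stim_means.tau_bias)
        adapt = stim_means.va_high * (1 + math.exp(-1 / stim_means.tau_va))
        drift = stim_means.v_snr * 0.5 + stim_means.v_0 \
            + stim_means.v_bias * pt + adapt * 0.5
        assert d.pt_bias == pytest.approx(pt)
        assert d.adapt == pytest.approx(adapt)
        assert d.drift == pytest.approx(drift)
        assert d.ndt == pytest.approx(
            stim_means.ndt_0 + stim_means.ndt_bias * abs(pt))
        assert d.start_frac == pytest.approx(
            1 / (1 + math.exp(-(stim_means.z_0 + stim_means.z_bias * pt))))

    def test_missing_context_errors(self, rule_means, stim_means):
        with pytest.raises(ValueError):
            td.trial_drivers(rule_means, make_trial(cue=None), "rule")
        with pytest.raises(ValueError):
            td.trial_drivers(stim_means,
                             make_trial(session_type="stim", cue=None), "stim")


class TestSolver:
    def test_symmetric_case(self):
        d = TrialDrivers(drift=0.0, start_frac=0.5, bound_half=1.0,
                         collapse=0.0, ndt=0.0, window=8.0)
        sol = solve_fpt(d)
        assert sol.p_upper() == pytest.approx(0.5, abs=0.002)

    def test_constant_drift_closed_form(self):
        d = TrialDrivers(drift=1.0, start_frac=0.5, bound_half=0.5,
                         collapse=0.0, ndt=0.0, window=8.0)
        sol = solve_fpt(d)
        assert sol.p_upper() == pytest.approx(1 / (1 + math.exp(-1)),
                                              abs=0.003)

    def test_mass_conservation_across_driver_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            d = TrialDrivers(drift=float(rng.uniform(-6, 6)),
                             start_frac=float(rng.uniform(0.1, 0.9)),
                             bound_half=float(rng.uniform(0.4, 1.6)),
                             collapse=float(rng.uniform(0, 1.2)),
                             ndt=0.0, window=2.0)
            sol = solve_fpt(d)
            assert sol.total_mass() == pytest.approx(1.0, abs=1e-3)
            assert sol.dens_upper.min() >= -1e-12
            assert sol.dens_lower.min() >= -1e-12

    def test_mirror_symmetry(self):
        a = solve_fpt(TrialDrivers(drift=1.3, start_frac=0.3, bound_half=1.0,
                                   collapse=0.4, ndt=0.0, window=2.0))
        b = solve_fpt(TrialDrivers(drift=-1.3, start_frac=0.7, bound_half=1.0,
                                   collapse=0.4, ndt=0.0, window=2.0))
        np.testing.assert_allclose(a.dens_upper, b.dens_lower, rtol=1e-6,
                                   atol=1e-9)
        np.testing.assert_allclose(a.dens_lower, b.dens_upper, rtol=1e-6,
                                   atol=1e-9)

    def test_p_upper_increasing_in_drift(self):
        ps = [solve_fpt(TrialDrivers(drift=mu, start_frac=0.4, bound_half=0.9,
                                     collapse=0.5, ndt=0.0,
                                     window=2.0)).p_upper()
              for mu in np.linspace(-3, 3, 7)]
        assert np.all(np.diff(ps) > 0)

    def test_collapsed_bound_forces_absorption(self):
        # bound hits zero at t = 0.5 << window: no undecided mass remains
        sol = solve_fpt(TrialDrivers(drift=0.0, start_frac=0.5, bound_half=0.5,
                                     collapse=1.0, ndt=0.0, window=2.0))
        assert sol.undecided_mass == pytest.approx(0.0, abs=1e-9)
        assert sol.time_grid[np.argmax(sol.dens_upper)] <= 0.6


class TestRtLikelihood:
    def test_pure_lapse_uniform(self, rule_means):
        from dataclasses import replace
        p = replace(rule_means, lapse=0.5)  # max allowed; formula is linear
        t = make_trial(choice="H", rt=0.8, cue="high")
        val = td.rt_likelihood(p, t)
        ddm_part = td.rt_likelihood(replace(rule_means, lapse=0.0), t)
        assert val == pytest.approx(0.5 * ddm_part + 0.5 / 4.0, rel=1e-6)

    def test_zero_before_ndt(self, rule_means):
        from dataclasses import replace
        p = replace(rule_means, lapse=0.0)
        t = make_trial(choice="H", rt=0.1, cue="high")  # below ndt_0 = 0.27
        assert td.rt_likelihood(p, t) == 0.0

    def test_density_normalization(self, rule_means):
        t = make_trial(choice="H", rt=0.5, cue="high")
        drv = td.trial_drivers(rule_means, t)
        sol = solve_fpt(drv, horizon=t.response_window - drv.ndt)
        total = (sol.p_upper() + sol.p_lower()) * (1 - rule_means.lapse) \
            + rule_means.lapse + (1 - rule_means.lapse) * sol.undecided_mass
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_invalid_rt_rejected(self, rule_means):
        # the trial schema itself enforces rt within (0, window] ...
        with pytest.raises(ValueError):
            make_trial(choice="H", rt=2.5, cue="high")
        # ... and the likelihood refuses unresponded trials
        with pytest.raises(ValueError):
            td.rt_likelihood(rule_means, make_trial(cue="high"))


class TestSimulation:
    def test_strong_drift_limit(self):
        ch, _ = simulate_paths_core(10.0, 0.5, 0.0, 0.0, 2.0, 1e-3, 1000, 42)
        assert (ch == 1).mean() > 0.95

    def test_fixed_seed_reproducible(self, rule_means):
        t = make_trial(cue="high")
        a = td.simulate_trials(rule_means, [t] * 50, np.random.default_rng(5))
        b = td.simulate_trials(rule_means, [t] * 50, np.random.default_rng(5))
        assert [(x.choice, x.rt) for x in a] == [(x.choice, x.rt) for x in b]

    def test_simulator_matches_solver(self):
        """Euler paths and the Crank-Nicolson densities agree (KS < 0.01)."""
        drv = TrialDrivers(drift=1.0, start_frac=0.5, bound_half=1.0,
                           collapse=0.5, ndt=0.0, window=2.0)
        sol = solve_fpt(drv)
        ch, ts = simulate_paths_core(1.0, 1.0, 0.5, 0.0, 2.0, 2.5e-4,
                                     50_000, 7)
        assert abs((ch == 1).mean() - sol.p_upper()) < 0.01
        for sign, dens, p in ((1, sol.dens_upper, sol.p_upper()),
                              (-1, sol.dens_lower, sol.p_lower())):
            samp = np.sort(ts[ch == sign])
            cdf_model = np.cumsum(dens) * sol.dt / p
            cdf_emp = np.searchsorted(samp, sol.time_grid, "right") / samp.size
            assert np.abs(cdf_model - cdf_emp).max() < 0.01

    def test_lapse_trials_mixed_in(self, rule_means):
        from dataclasses import replace
        p = replace(rule_means, lapse=1.0 if False else 0.5)
        t = make_trial(cue="low", snr_db=-6.0, tone="H")
        out = td.simulate_trials(p, [t] * 400, np.random.default_rng(9))
        rts = np.array([x.rt for x in out if x.choice != "none"])
        # with a 50% uniform lapse the RT distribution gains early/late mass
        assert (rts > 1.5).mean() > 0.05


def test_params_json_round_trip(tmp_path, stim_means):
    path = tmp_path / "p.json"
    stim_means.to_json(path)
    back = td.DDMParams.from_json(path)
    assert back == stim_means
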