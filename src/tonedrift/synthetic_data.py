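"""Synthetic cohorts: behavior and pupil traces with the structure the
analysis pipeline assumes.

Subject-level DDM parameters are drawn around published across-subject
means/SDs for each condition (time constants stored as inverse rates, as the
summary tables report them), with an explicit negative coupling between the
rule-based starting-point and evidence biases.  Behavior is simulated from
the generative DDM on sessions built by :mod:`tonedrift.task_design`; pupil
recordings add a choice-locked gamma-shaped transient whose amplitude is
larger on prior-incongruent trials (rule condition), plus drift, blinks,
sensor noise and gaze jitter at 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import ddm, task_design
from .ddm import DDMParams
from .fitting import SEARCH_BOXES
from .psychometrics import congruence_label
from .pupil import PupilRecording
from .task_design import SessionDesign, Trial, generate_session

__all__ = ["PARAM_TABLE", "CohortSpec", "sample_subject_params",
           "generate_behavior", "generate_pupil", "table_means"]

#: across-subject (mean, SD) of best-fitting parameters per condition.
#: tau entries are inverse time constants (decay rates per tone position).
PARAM_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "rule": {
        "v_snr": (6.51, 3.36), "B": (0.92, 0.26), "t_B": (0.92, 0.48),
        "ndt_0": (0.27, 0.08), "lapse": (0.02, 0.01),
        "v_low": (-0.83, 0.79), "v_0": (0.07, 0.41), "v_high": (0.67, 0.71),
        "z_low": (-0.20, 0.31), "z_0": (0.06, 0.22), "z_high": (0.39, 0.31),
    },
    "stim": {
        "v_snr": (4.97, 2.55), "B": (1.02, 0.27), "t_B": (0.80, 0.33),
        "ndt_0": (0.46, 0.07), "ndt_bias": (-0.12, 0.29),
        "lapse": (0.02, 0.02), "v_0": (-0.20, 0.62), "v_bias": (0.84, 0.73),
        "tau_bias_inv": (4.99, 4.89), "va_low": (-2.31, 1.81),
        "va_high": (-1.40, 1.75), "tau_va_inv": (7.04, 6.25),
        "z_0": (-0.03, 0.19), "z_bias": (-0.09, 0.16),
    },
    "mixed1": {
        "v_snr": (4.40, 2.34), "B": (1.06, 0.21), "t_B": (1.01, 0.38),
        "ndt_0": (0.38, 0.05), "ndt_bias": (-0.12, 0.32),
        "lapse": (0.02, 0.01), "v_low": (-1.60, 0.85), "v_high": (1.59, 0.93),
        "v_bias": (0.83, 0.60), "tau_bias_inv": (6.82, 5.24),
        "va_low": (-2.05, 1.83), "va_high": (-1.53, 1.67),
        "tau_va_inv": (9.84, 5.45), "z_low": (-0.12, 0.36),
        "z_high": (0.13, 0.33), "z_bias": (-0.11, 0.10),
    },
    "mixed2": {
        "v_snr": (5.46, 3.21), "B": (0.93, 0.17), "t_B": (0.87, 0.45),
        "ndt_0": (0.07, 0.07), "ndt_bias": (-0.17, 0.29),
        "lapse": (0.02, 0.01), "v_low": (-1.36, 0.91), "v_0": (-0.19, 0.61),
        "v_high": (1.19, 1.04), "v_bias": (0.80, 0.49),
        "tau_bias_inv": (7.80, 5.11), "va_low": (-1.97, 1.37),
        "va_high": (-1.68, 1.22), "tau_va_inv": (8.74, 5.97),
        "z_low": (0.00, 0.30), "z_0": (0.02, 0.24), "z_high": (0.03, 0.35),
        "z_bias": (-0.03, 0.17),
    },
}

#: rule-based (z, v) bias pairs coupled in the generator
_COUPLED_PAIRS = (("z_low", "v_low"), ("z_0", "v_0"), ("z_high", "v_high"))


def table_means(condition: str) -> DDMParams:
    """DDMParams at the across-subject means for one condition."""
    kw = {}
    for name, (mean, _) in PARAM_TABLE[condition].items():
        if name == "tau_bias_inv":
            kw["tau_bias"] = 1.0 / mean
        elif name == "tau_va_inv":
            kw["tau_va"] = 1.0 / mean
        else:
            kw[name] = mean
    return DDMParams(**kw)


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort."""

    n_subjects: int = 10
    conditions: tuple[str, ...] = ("rule", "stim")
    param_means: dict[str, dict[str, float]] = field(default_factory=dict)
    param_sds: dict[str, dict[str, float]] = field(default_factory=dict)
    coupling: float = -0.6       # corr(z_c, v_c) for rule-based bias pairs
    pupil_effect: float = 0.3    # incongruent-congruent transient (z units)
    pupil_window_ms: tuple[int, int] = (200, 800)
    blink_rate_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [-1, 1]")
        for cond, d in self.param_sds.items():
            if any(sd < 0 for sd in d.values()):
                raise ValueError("param SDs must be non-negative")

    def moments(self, condition: str) -> dict[str, tuple[float, float]]:
        base = dict(PARAM_TABLE[condition])
        means = self.param_means.get(condition, {})
        sds = self.param_sds.get(condition, {})
        out = {}
        for name, (m, s) in base.items():
            out[name] = (means.get(name, m), sds.get(name, s))
        return out


_BOX_ALIASES = {"tau_bias_inv": "tau_bias_inv", "tau_va_inv": "tau_va_inv"}


def _truncate(rng, mean, sd, lo, hi, max_tries=1000):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_subject_params(spec: CohortSpec, rng: np.random.Generator,
                          condition: str) -> DDMParams:
    """Draw one subject's generative parameters.

    Independent truncated Gaussians at the table moments, except the
    rule-based (z_c, v_c) pairs which share a bivariate Gaussian with
    correlation ``spec.coupling``; all values respect the fitting search
    boxes (resampled on violation).
    """
    mom = spec.moments(condition)
    draws: dict[str, float] = {}
    coupled = [p for p in _COUPLED_PAIRS
               if p[0] in mom and p[1] in mom] if condition != "stim" else []
    coupled_names = {n for p in coupled for n in p}
    for name, (m, s) in mom.items():
        if name in coupled_names:
            continue
        lo, hi = SEARCH_BOXES[name]
        draws[name] = _truncate(rng, m, s, lo, hi)
    for zn, vn in coupled:
        mz, sz = mom[zn]
        mv, sv = mom[vn]
        cov = spec.coupling * sz * sv
        for _ in range(1000):
            z, v = rng.multivariate_normal([mz, mv],
                                           [[sz**2, cov], [cov, sv**2]])
            if (SEARCH_BOXES[zn][0] <= z <= SEARCH_BOXES[zn][1]
                    and SEARCH_BOXES[vn][0] <= v <= SEARCH_BOXES[vn][1]):
                break
        else:
            z, v = mz, mv
        draws[zn], draws[vn] = float(z), float(v)
    kw = {}
    for name, val in draws.items():
        if name == "tau_bias_inv":
            kw["tau_bias"] = 1.0 / val
        elif name == "tau_va_inv":
            kw["tau_va"] = 1.0 / val
        else:
            kw[name] = val
    return DDMParams(**kw)


def generate_behavior(spec: CohortSpec, designs: dict[str, SessionDesign]
                      | None = None, dt_sim: float = 1e-3
                      ) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort; returns (trial table, ground truth).

    Ground truth maps (subject_id, condition) -> DDMParams.  Simulated
    window expiries are re-drawn up to 5 times before being recorded as
    choice = "none".
    """
    rng = np.random.default_rng(spec.seed)
    designs = designs or {}
    frames = []
    truth: dict[tuple[str, str], DDMParams] = {}
    for s in range(spec.n_subjects):
        sid = f"S{s:02d}"
        for cond in spec.conditions:
            params = sample_subject_params(spec, rng, cond)
            truth[(sid, cond)] = params
            design = designs.get(cond, SessionDesign.default(cond))
            stimuli = generate_session(design, rng, subject_id=sid)
            # no-pretest trials are presented but never analyzed (nor do the
            # stimulus-based bias terms apply); leave them unresponded
            playable = set(id(t) for t in task_design.filter_analyzable(stimuli))
            todo = [t for t in stimuli if id(t) in playable]
            done_map = {}
            sim = ddm.simulate_trials(params, todo, rng, dt_sim=dt_sim)
            for attempt in range(5):
                redo = [i for i, t in enumerate(sim) if t.choice == "none"]
                if not redo:
                    break
                redone = ddm.simulate_trials(params, [todo[i] for i in redo],
                                             rng, dt_sim=dt_sim)
                for i, t in zip(redo, redone):
                    sim[i] = t
            for src, t in zip(todo, sim):
                done_map[id(src)] = t
            done = [done_map.get(id(t), t) for t in stimuli]
            frames.append(task_design.trials_to_frame(done))
    table = pd.concat(frames, ignore_index=True)
    return table, truth


def _gamma_kernel(n_ms: int = 2500, shape: float = 2.0,
                  scale_ms: float = 300.0) -> np.ndarray:
    t = np.arange(n_ms, dtype=float)
    k = t ** (shape - 1.0) * np.exp(-t / scale_ms)
    return k / k.max()


def generate_pupil(trials: Sequence[Trial], spec: CohortSpec,
                   rng: np.random.Generator, iti_ms: int = 1500,
                   pre_ms: int = 1000) -> PupilRecording:
    """Build one 1000-Hz recording covering the given (responded) trials.

    Each trial contributes a choice-locked transient (gamma kernel, shape 2,
    scale 300 ms) of unit amplitude, plus ``spec.pupil_effect`` extra on
    trials whose choice is incongruent with a rule-based cue.  Baseline
    drift is a smoothed random walk; blinks arrive as a Poisson process and
    zero out 100-150 ms of samples.
    """
    trials = [t for t in trials if t.choice in ("L", "H")]
    if not trials:
        raise ValueError("no responded trials to build a recording from")
    kernel = _gamma_kernel()
    onsets, choices = [], []
    cursor = pre_ms
    for t in trials:
        n_pre = len(t.pretest)
        onset = cursor + 400 * n_pre  # 300 ms bursts + 100 ms gaps
        onsets.append(onset)
        choices.append(onset + int(round(1000 * t.rt)))
        cursor = choices[-1] + iti_ms
    n = cursor + 2500
    time = np.arange(n)

    diam = np.zeros(n)
    # slow baseline drift: heavily smoothed white noise
    steps = rng.normal(0, 1.0, n // 250 + 2)
    diam += np.interp(time, np.arange(steps.size) * 250, np.cumsum(steps) * 0.05)
    for t, ch in zip(trials, choices):
        amp = 1.0
        if congruence_label(t) == "incongruent" and t.cue is not None:
            amp += spec.pupil_effect
        seg = min(kernel.size, n - ch)
        diam[ch:ch + seg] += amp * kernel[:seg]
    diam = 3000.0 + 400.0 * diam + rng.normal(0, 2.0, n)

    missing = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(spec.blink_rate_hz * n / 1000.0)
    for start in rng.integers(0, max(n - 200, 1), size=n_blinks):
        missing[start:start + int(rng.integers(100, 151))] = True
    diam[missing] = 0.0

    gaze_x = rng.normal(0, 0.5, n)
    gaze_y = rng.normal(0, 0.5, n)

    events = pd.DataFrame({
        "trial_index": [t.trial_index for t in trials],
        "tone_onset_ms": onsets,
        "choice_ms": choices,
    })
    return PupilRecording(t_ms=time, diameter=diam, gaze_x=gaze_x,
                          gaze_y=gaze_y, missing_mask=missing, events=events)
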