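"""Generalized drift-diffusion model for expectation-biased tone discrimination.

The decision variable x accumulates noisy evidence, dx = v dt + sigma dW with
sigma = 1, between absorbing bounds that collapse linearly: commitment occurs
when |x(t)| >= B - t_B t (upper bound = high-frequency choice).  The drift is

    v = v_SNR * SNR + bias_evidence + adapt * |SNR|

where bias_evidence carries rule-based (per-cue) or stimulus-based
(pre-test-sequence) biases and the adapt term is the SNR-proportional,
adaptation-like repulsion driven by recent tone history.  The starting point
is x0 = bias_start * 2B measured from the lower bound, with bias_start the
logistic transform of a (possibly sequence-dependent) logit-scale bias.
Non-decision time is ndt = ndt_0 + ndt_Bias * |pt_Bias|, and a lapse mixes a
uniform (choice, RT) distribution into the predicted RT distribution with
weight lambda.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

from ._kernels import simulate_paths_core, simulate_trials_core, solve_fpt_core
from .task_design import Trial

__all__ = [
    "DDMParams",
    "TrialDrivers",
    "FirstPassageSolution",
    "compute_pt_bias",
    "compute_adapt",
    "trial_drivers",
    "solve_fpt",
    "rt_likelihood",
    "simulate_trial",
    "simulate_trials",
    "logistic",
]

#: default solver resolution (seconds / evidence units)
DEFAULT_DT = 0.005
DEFAULT_DX = 0.005
START_FRAC_CLIP = (0.01, 0.99)


def logistic(y: float) -> float:
    """g(y) = 1 / (1 + e^-y), the transform keeping bias_start in (0, 1)."""
    return 1.0 / (1.0 + math.exp(-y))


@dataclass(frozen=True)
class DDMParams:
    """Full parameter vector; variant lattices freeze subsets of these.

    Time constants ``tau_bias`` and ``tau_va`` are expressed in units of tone
    positions (the exponential weights are e^(-position/tau)); parameter
    tables conventionally report their inverses (decay rates).
    """

    v_snr: float = 5.0        # drift gain (1 / unit-SNR / s)
    B: float = 1.0            # half total bound height
    t_B: float = 0.0          # linear bound collapse rate (height / s)
    ndt_0: float = 0.3        # non-decision time (s)
    ndt_bias: float = 0.0     # extra ndt per |pt_bias| (s)
    lapse: float = 0.0        # uniform-mixture weight, in [0, 0.5]
    v_low: float = 0.0        # rule-based evidence biases per cue
    v_0: float = 0.0
    v_high: float = 0.0
    v_bias: float = 0.0       # stimulus-based evidence gain on pt_bias
    tau_bias: float = 1.0     # pt_bias time constant (tone positions)
    va_low: float = 0.0       # adaptation weights (low / high tones)
    va_high: float = 0.0
    tau_va: float = 1.0       # adaptation time constant
    z_low: float = 0.0        # rule-based starting-point biases (logit scale)
    z_0: float = 0.0
    z_high: float = 0.0
    z_bias: float = 0.0       # stimulus-based starting-point gain
    sigma: float = 1.0        # instantaneous noise, fixed
    v_width: float = 0.0      # uniform drift-variability width (variant only)

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.t_B < 0 or self.ndt_0 < 0:
            raise ValueError("t_B and ndt_0 must be non-negative")
        if not (0.0 <= self.lapse <= 0.5):
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.tau_bias <= 0 or self.tau_va <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma != 1.0:
            raise ValueError("sigma is fixed at 1")

    # --- JSON round-trip (table-style symbol names) -----------------------
    _SYMBOLS = {
        "v_SNR": "v_snr", "B": "B", "t_B": "t_B", "ndt_0": "ndt_0",
        "ndt_Bias": "ndt_bias", "lapse": "lapse", "v_Low": "v_low",
        "v_0": "v_0", "v_High": "v_high", "v_Bias": "v_bias",
        "tau_Bias": "tau_bias", "va_Low": "va_low", "va_High": "va_high",
        "tau_va": "tau_va", "z_Low": "z_low", "z_0": "z_0",
        "z_High": "z_high", "z_Bias": "z_bias", "v_width": "v_width",
    }

    def to_dict(self) -> dict[str, float]:
        inv = {v: k for k, v in self._SYMBOLS.items()}
        return {inv[f.name]: getattr(self, f.name)
                for f in fields(self) if f.name in inv}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DDMParams":
        kw = {cls._SYMBOLS[k]: float(v) for k, v in d.items()
              if k in cls._SYMBOLS}
        return cls(**kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DDMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TrialDrivers:
    """Per-trial derived quantities feeding the first-passage solver."""

    drift: float
    start_frac: float       # bias_start in (0, 1)
    bound_half: float       # B
    collapse: float         # t_B
    ndt: float
    window: float
    pt_bias: float = 0.0
    adapt: float = 0.0
    v_width: float = 0.0

    @property
    def x0(self) -> float:
        """Start position measured from the lower bound (= start_frac * 2B)."""
        return self.start_frac * 2.0 * self.bound_half


@dataclass(frozen=True)
class FirstPassageSolution:
    """Choice-conditional defect densities of decision time t_s."""

    time_grid: np.ndarray
    dens_upper: np.ndarray
    dens_lower: np.ndarray
    undecided_mass: float
    dt: float

    def p_upper(self) -> float:
        return float(np.sum(self.dens_upper) * self.dt)

    def p_lower(self) -> float:
        return float(np.sum(self.dens_lower) * self.dt)

    def total_mass(self) -> float:
        return self.p_upper() + self.p_lower() + self.undecided_mass

    def density_at(self, choice: str, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the decision-time density (0 outside grid)."""
        dens = self.dens_upper if choice == "H" else self.dens_lower
        return np.interp(t, self.time_grid, dens, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# sequence-history terms

def _position_weights(pretest: Sequence[str], tau: float) -> tuple[float, float]:
    """Sums of e^(-p/tau) over high and low tones, positions numbered in
    reverse chronological order starting at 0 (the tone just before the test
    tone has position 0)."""
    s_high = s_low = 0.0
    n = len(pretest)
    for pos, tone in enumerate(reversed(pretest)):
        w = math.exp(-pos / tau)
        if tone == "H":
            s_high += w
        else:
            s_low += w
    return s_high, s_low


def compute_pt_bias(pretest: Sequence[str], tau_bias: float) -> float:
    """Exponentially weighted tally of pre-test tones: high minus low."""
    if tau_bias <= 0:
        raise ValueError("tau_bias must be positive")
    s_high, s_low = _position_weights(pretest, tau_bias)
    return s_high - s_low


def compute_adapt(pretest: Sequence[str], va_high: float, va_low: float,
                  tau_va: float) -> float:
    """Adaptation drive: va_High * sum_high e^(-p/tau) - va_Low * sum_low e^(-p/tau)."""
    if tau_va <= 0:
        raise ValueError("tau_va must be positive")
    s_high, s_low = _position_weights(pretest, tau_va)
    return va_high * s_high - va_low * s_low


def trial_drivers(params: DDMParams, trial: Trial,
                  condition_role: str | None = None) -> TrialDrivers:
    """Compose the per-trial drift, starting fraction, and non-decision time.

    ``condition_role`` selects which bias machinery applies: "rule" (per-cue
    biases), "stim" (sequence-dependent biases plus adaptation), or "mixed"
    (both).  Defaults to the trial's session type.
    """
    role = condition_role or {"rule": "rule", "stim": "stim",
                              "mixed1": "mixed", "mixed2": "mixed"}[trial.session_type]
    pt_bias = adapt = 0.0
    bias_ev = 0.0
    z_logit = params.z_0

    if role in ("rule", "mixed"):
        if trial.cue is None:
            raise ValueError("rule-based drivers require a cue")
        bias_ev += {"low": params.v_low, "neutral": params.v_0,
                    "high": params.v_high}[trial.cue.label]
        z_logit = {"low": params.z_low, "neutral": params.z_0,
                   "high": params.z_high}[trial.cue.label]
    if role in ("stim", "mixed"):
        if len(trial.pretest) == 0:
            raise ValueError("stimulus-based drivers require a pre-test sequence")
        pt_bias = compute_pt_bias(trial.pretest, params.tau_bias)
        adapt = compute_adapt(trial.pretest, params.va_high, params.va_low,
                              params.tau_va)
        if role == "stim":
            bias_ev += params.v_0 + params.v_bias * pt_bias
            z_logit = params.z_0 + params.z_bias * pt_bias
        else:  # mixed: cue terms above plus sequence terms
            bias_ev += params.v_bias * pt_bias
            z_logit = z_logit + params.z_bias * pt_bias

    drift = params.v_snr * trial.snr_unit + bias_ev + adapt * abs(trial.snr_unit)
    start = min(max(logistic(z_logit), START_FRAC_CLIP[0]), START_FRAC_CLIP[1])
    ndt = max(params.ndt_0 + params.ndt_bias * abs(pt_bias), 0.0)
    return TrialDrivers(
        drift=drift, start_frac=start, bound_half=params.B,
        collapse=params.t_B, ndt=ndt, window=trial.response_window,
        pt_bias=pt_bias, adapt=adapt, v_width=params.v_width,
    )


# ---------------------------------------------------------------------------
# first-passage solution and likelihood

def solve_fpt(drivers: TrialDrivers, dt: float = DEFAULT_DT,
              dx: float = DEFAULT_DX, horizon: float | None = None
              ) -> FirstPassageSolution:
    """Crank-Nicolson forward solution of the bounded diffusion.

    Returns choice-conditional decision-time densities on a uniform time grid
    up to ``horizon`` (defaults to the trial's response window).  If the bound
    collapses to zero before the horizon, all remaining mass is absorbed there
    (split by the sign of the decision variable).
    """
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    T = horizon if horizon is not None else drivers.window
    x0 = (drivers.start_frac - 0.5) * 2.0 * drivers.bound_half
    up, lo, und = solve_fpt_core(drivers.drift, drivers.bound_half,
                                 drivers.collapse, x0, dt, dx, T)
    t = dt * np.arange(1, up.shape[0] + 1)
    return FirstPassageSolution(time_grid=t, dens_upper=up, dens_lower=lo,
                                undecided_mass=und, dt=dt)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


def _fpt_solutions_for(drivers: TrialDrivers, dt: float, dx: float,
                       drift_variability: bool) -> list[tuple[float, FirstPassageSolution]]:
    """(weight, solution) pairs; several pairs under drift variability."""
    if not drift_variability or drivers.v_width == 0.0:
        return [(1.0, solve_fpt(drivers, dt, dx))]
    half = drivers.v_width / 2.0
    out = []
    for node, w in zip(_GL_NODES, _GL_WEIGHTS):
        d = replace(drivers, drift=drivers.drift + node * half)
        out.append((w / 2.0, solve_fpt(d, dt, dx)))
    return out


def rt_likelihood(params: DDMParams, trial: Trial,
                  condition_role: str | None = None,
                  drift_variability: bool = False,
                  dt: float = DEFAULT_DT, dx: float = DEFAULT_DX,
                  solution: FirstPassageSolution | None = None) -> float:
    """Predicted density of the observed (choice, rt) pair.

    density = (1 - lambda) f_DDM(choice, rt - ndt) + lambda / (2 window),
    with f_DDM zero for rt < ndt.  Under the drift-variability variant the
    DDM density is averaged over a uniform drift interval of width v_width
    (15-point Gauss-Legendre).  A pre-computed ``solution`` for the trial's
    drivers may be supplied to skip the solve (not valid with variability).
    """
    if trial.choice not in ("L", "H"):
        raise ValueError("rt_likelihood needs a committed choice")
    if not (0.0 < trial.rt <= trial.response_window):
        raise ValueError("rt outside (0, response_window]")
    drivers = trial_drivers(params, trial, condition_role)
    lam = params.lapse
    f = 0.0
    ts = trial.rt - drivers.ndt
    if ts > 0:
        if solution is not None and not drift_variability:
            f = float(solution.density_at(trial.choice, ts))
        else:
            for w, sol in _fpt_solutions_for(drivers, dt, dx, drift_variability):
                f += w * float(sol.density_at(trial.choice, ts))
    return (1.0 - lam) * f + lam / (2.0 * trial.response_window)


# ---------------------------------------------------------------------------
# simulation

def simulate_trial(drivers: TrialDrivers, rng: np.random.Generator,
                   dt_sim: float = 1e-3, lapse: float = 0.0
                   ) -> tuple[str, float] | None:
    """Simulate one trial; returns (choice, rt) or None for window expiry.

    With probability ``lapse`` the outcome is replaced by a uniform lapse draw
    over both choices and (0, window].
    """
    if lapse > 0 and rng.random() < lapse:
        choice = "H" if rng.random() < 0.5 else "L"
        return choice, float(rng.uniform(0.0, drivers.window))
    seed = int(rng.integers(0, 2**31 - 1))
    x0 = (drivers.start_frac - 0.5) * 2.0 * drivers.bound_half
    ch, ts = simulate_paths_core(drivers.drift, drivers.bound_half,
                                 drivers.collapse, x0,
                                 drivers.window - drivers.ndt, dt_sim, 1, seed)
    if ch[0] == 0:
        return None
    rt = float(ts[0]) + drivers.ndt
    if rt > drivers.window:
        return None
    return ("H" if ch[0] == 1 else "L"), rt


def simulate_trials(params: DDMParams, trials: Iterable[Trial],
                    rng: np.random.Generator, dt_sim: float = 1e-3,
                    condition_role: str | None = None) -> list[Trial]:
    """Vectorized simulation of a full session; returns completed trials.

    Lapse trials are drawn first, the rest share one compiled Euler sweep.
    Window expiry yields choice = "none" with rt = NaN.
    """
    trials = list(trials)
    n = len(trials)
    drivers = [trial_drivers(params, t, condition_role) for t in trials]
    lapse_mask = rng.random(n) < params.lapse
    seed = int(rng.integers(0, 2**31 - 1))
    drifts = np.array([d.drift for d in drivers])
    Bs = np.array([d.bound_half for d in drivers])
    tBs = np.array([d.collapse for d in drivers])
    x0s = np.array([(d.start_frac - 0.5) * 2.0 * d.bound_half for d in drivers])
    windows = np.array([d.window for d in drivers])
    ndts = np.array([d.ndt for d in drivers])
    ch, rts = simulate_trials_core(drifts, Bs, tBs, x0s, windows, ndts,
                                   dt_sim, seed)
    out = []
    for i, t in enumerate(trials):
        if lapse_mask[i]:
            choice = "H" if rng.random() < 0.5 else "L"
            rt = float(rng.uniform(np.nextafter(0.0, 1.0), t.response_window))
        elif ch[i] == 0:
            choice, rt = "none", float("nan")
        else:
            choice, rt = ("H" if ch[i] == 1 else "L"), float(rts[i])
        out.append(replace(t, choice=choice, rt=rt,
                           correct=(choice == t.tone)))
    return out
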