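"""Per-subject maximum-likelihood estimation of the DDM variant lattice.

Each variant frees a subset of the full parameter vector; all variants are fit
to the joint (choice, RT) distribution by differential evolution within fixed
search boxes, followed by a local polish.  The likelihood of a trial set is
evaluated by solving the first-passage problem once per unique
(drift, starting-point) pair and interpolating the defect densities at each
trial's decision time.

The decay time constants are fitted on the inverse (rate) scale, matching the
convention of parameter summary tables; rule-based starting points are fitted
on the logit scale throughout (bias_start = g(z_c)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import ddm
from ._kernels import solve_fpt_batch
from .ddm import DDMParams, START_FRAC_CLIP
from .task_design import Trial

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "get_variant",
    "FitResult",
    "fit_subject",
    "dataset_loglik",
    "likelihood_ratio_test",
    "classify_subject",
]

#: search boxes per free parameter (generously covering published fits)
SEARCH_BOXES: dict[str, tuple[float, float]] = {
    "v_snr": (0.0, 20.0),
    "B": (0.3, 3.0),
    "t_B": (0.0, 3.0),
    "ndt_0": (0.0, 1.0),
    "ndt_bias": (-1.0, 1.0),
    "lapse": (0.0, 0.2),
    "v_low": (-5.0, 5.0),
    "v_0": (-5.0, 5.0),
    "v_high": (-5.0, 5.0),
    "v_bias": (-5.0, 5.0),
    "tau_bias_inv": (0.2, 20.0),
    "va_low": (-8.0, 8.0),
    "va_high": (-8.0, 8.0),
    "tau_va_inv": (0.2, 20.0),
    "z_low": (-5.0, 5.0),
    "z_0": (-5.0, 5.0),
    "z_high": (-5.0, 5.0),
    "z_bias": (-5.0, 5.0),
    "v_width": (0.0, 10.0),
}

_COMMON = ["v_snr", "B", "v_0", "z_0", "ndt_0", "lapse"]
_RULE_BIAS = ["v_low", "v_high", "z_low", "z_high"]
_STIM_BIAS = ["v_bias", "z_bias", "tau_bias_inv", "ndt_bias"]
_STIM_ADAPT = ["va_low", "va_high", "tau_va_inv"]


@dataclass(frozen=True)
class ModelVariant:
    """A named point on the variant lattice: which parameters are free."""

    name: str
    condition: str  # rule | stim | mixed
    free_params: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.free_params)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [SEARCH_BOXES[p] for p in self.free_params]

    def build_params(self, theta: Sequence[float]) -> DDMParams:
        kw: dict[str, float] = {}
        for name, val in zip(self.free_params, theta):
            if name == "tau_bias_inv":
                kw["tau_bias"] = 1.0 / val
            elif name == "tau_va_inv":
                kw["tau_va"] = 1.0 / val
            else:
                kw[name] = float(val)
        return DDMParams(**kw)

    def theta_of(self, params: DDMParams) -> np.ndarray:
        out = []
        for name in self.free_params:
            if name == "tau_bias_inv":
                out.append(1.0 / params.tau_bias)
            elif name == "tau_va_inv":
                out.append(1.0 / params.tau_va)
            else:
                out.append(getattr(params, name))
        return np.asarray(out, dtype=float)

    def is_nested_in(self, other: "ModelVariant") -> bool:
        return (self.condition == other.condition
                and set(self.free_params) < set(other.free_params))


def _v(name, condition, params):
    return ModelVariant(name, condition, tuple(params))


VARIANTS: dict[tuple[str, str], ModelVariant] = {}
for _cond in ("rule", "stim"):
    VARIANTS[(_cond, "base")] = _v("base", _cond, _COMMON)
    VARIANTS[(_cond, "collapsing")] = _v("collapsing", _cond, _COMMON + ["t_B"])
_rule_full = _COMMON + ["t_B"] + _RULE_BIAS
_stim_full = _COMMON + ["t_B"] + _STIM_BIAS + _STIM_ADAPT
VARIANTS[("rule", "full")] = _v("full", "rule", _rule_full)
VARIANTS[("rule", "evidence_only")] = _v(
    "evidence_only", "rule", [p for p in _rule_full if p not in ("z_low", "z_high")])
VARIANTS[("rule", "starting_point_only")] = _v(
    "starting_point_only", "rule", [p for p in _rule_full if p not in ("v_low", "v_high")])
VARIANTS[("rule", "full_fixed_bound")] = _v(
    "full_fixed_bound", "rule", [p for p in _rule_full if p != "t_B"])
VARIANTS[("rule", "drift_variability")] = _v(
    "drift_variability", "rule", [p for p in _rule_full if p != "t_B"] + ["v_width"])
VARIANTS[("stim", "full")] = _v("full", "stim", _stim_full)
VARIANTS[("stim", "bias_only")] = _v(
    "bias_only", "stim", [p for p in _stim_full if p not in _STIM_ADAPT])
VARIANTS[("stim", "evidence_only")] = _v(
    "evidence_only", "stim", [p for p in _stim_full if p != "z_bias"])
VARIANTS[("stim", "starting_point_only")] = _v(
    "starting_point_only", "stim", [p for p in _stim_full if p != "v_bias"])
VARIANTS[("mixed", "mixed_full")] = _v(
    "mixed_full", "mixed", _COMMON + ["t_B"] + _RULE_BIAS + _STIM_BIAS + _STIM_ADAPT)


def get_variant(condition: str, name: str) -> ModelVariant:
    try:
        return VARIANTS[(condition, name)]
    except KeyError:
        raise KeyError(f"no variant {name!r} for condition {condition!r}") from None


# ---------------------------------------------------------------------------
# vectorized dataset likelihood

_CUE_CODE = {"low": 0, "neutral": 1, "high": 2}


class _LikelihoodData:
    """Pre-digested trial arrays for fast repeated likelihood evaluation."""

    def __init__(self, trials: Sequence[Trial], condition: str,
                 dt: float = 0.01, dx: float = 0.01,
                 drift_round: float = 0.005, start_round: float = 0.002):
        trials = [t for t in trials
                  if t.choice in ("L", "H") and 0.0 < t.rt <= t.response_window]
        if not trials:
            raise ValueError("no analyzable (responded) trials")
        self.condition = condition
        self.n = len(trials)
        self.dt, self.dx = dt, dx
        self.drift_round, self.start_round = drift_round, start_round
        self.snr = np.array([t.snr_unit for t in trials])
        self.rt = np.array([t.rt for t in trials])
        self.window = np.array([t.response_window for t in trials])
        self.upper = np.array([t.choice == "H" for t in trials])
        if condition in ("rule", "mixed"):
            if any(t.cue is None for t in trials):
                raise ValueError("rule-based fits require a cue on every trial")
            self.cue = np.array([_CUE_CODE[t.cue.label] for t in trials])
        else:
            self.cue = None
        if condition in ("stim", "mixed"):
            if any(len(t.pretest) == 0 for t in trials):
                raise ValueError("stimulus-based fits require pre-test sequences")
            seqs: dict[tuple, int] = {}
            seq_id = np.empty(self.n, dtype=np.int64)
            for i, t in enumerate(trials):
                seq_id[i] = seqs.setdefault(t.pretest, len(seqs))
            pos, sign, owner = [], [], []
            for seq, sid in seqs.items():
                for p, tone in enumerate(reversed(seq)):
                    pos.append(p)
                    sign.append(1.0 if tone == "H" else -1.0)
                    owner.append(sid)
            self.seq_id = seq_id
            self.n_seq = len(seqs)
            self._pos = np.array(pos, dtype=float)
            self._sign = np.array(sign)
            self._owner = np.array(owner, dtype=np.int64)
        else:
            self.seq_id = None

    def _history_terms(self, params: DDMParams) -> tuple[np.ndarray, np.ndarray]:
        w_bias = np.exp(-self._pos / params.tau_bias)
        pt = np.bincount(self._owner, weights=self._sign * w_bias,
                         minlength=self.n_seq)
        w_va = np.exp(-self._pos / params.tau_va)
        va_w = np.where(self._sign > 0, params.va_high, -params.va_low) * w_va
        adapt = np.bincount(self._owner, weights=va_w, minlength=self.n_seq)
        return pt, adapt

    def drivers(self, params: DDMParams
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized per-trial (drift, start_frac, ndt)."""
        bias_ev = np.zeros(self.n)
        z_logit = np.full(self.n, params.z_0)
        ndt = np.full(self.n, params.ndt_0)
        if self.cue is not None:
            bias_ev += np.array([params.v_low, params.v_0, params.v_high])[self.cue]
            z_logit = np.array([params.z_low, params.z_0, params.z_high])[self.cue]
        if self.seq_id is not None:
            pt, adapt = self._history_terms(params)
            pt_t, adapt_t = pt[self.seq_id], adapt[self.seq_id]
            if self.condition == "stim":
                bias_ev += params.v_0 + params.v_bias * pt_t
                z_logit = params.z_0 + params.z_bias * pt_t
            else:
                bias_ev += params.v_bias * pt_t
                z_logit = z_logit + params.z_bias * pt_t
            ndt = np.maximum(params.ndt_0 + params.ndt_bias * np.abs(pt_t), 0.0)
        drift = params.v_snr * self.snr + bias_ev + adapt_t * np.abs(self.snr) \
            if self.seq_id is not None else params.v_snr * self.snr + bias_ev
        start = np.clip(1.0 / (1.0 + np.exp(-z_logit)), *START_FRAC_CLIP)
        return drift, start, ndt

    def loglik(self, params: DDMParams, drift_variability: bool = False,
               floor: float = 1e-10) -> float:
        drift, start, ndt = self.drivers(params)
        if drift_variability and params.v_width > 0:
            offsets = ddm._GL_NODES * params.v_width / 2.0
            weights = ddm._GL_WEIGHTS / 2.0
        else:
            offsets, weights = np.array([0.0]), np.array([1.0])
        T = float(self.window.max())
        f = np.zeros(self.n)
        dr = np.round(drift / self.drift_round) * self.drift_round
        sr = np.round(start / self.start_round) * self.start_round
        x0 = (sr - 0.5) * 2.0 * params.B
        ts = self.rt - ndt
        # fractional index into the density grid t = dt..n_steps*dt
        pos = ts / self.dt - 1.0
        i0 = np.floor(pos).astype(np.int64)
        frac = pos - i0
        for off, w in zip(offsets, weights):
            keys = np.stack([dr + off, x0], axis=1)
            uniq, inv = np.unique(keys, axis=0, return_inverse=True)
            dup, dlo, _ = solve_fpt_batch(
                np.ascontiguousarray(uniq[:, 0]),
                np.ascontiguousarray(uniq[:, 1]),
                params.B, params.t_B, self.dt, self.dx, T)
            dens_mat = np.where(self.upper[:, None], dup[inv], dlo[inv])
            n_steps = dup.shape[1]
            lo_i = np.clip(i0, 0, n_steps - 1)
            hi_i = np.clip(i0 + 1, 0, n_steps - 1)
            rows = np.arange(self.n)
            vals = ((1.0 - frac) * dens_mat[rows, lo_i]
                    + frac * dens_mat[rows, hi_i])
            vals[(pos < 0) | (pos > n_steps - 1) | (ts <= 0)] = 0.0
            f += w * vals
        dens = (1.0 - params.lapse) * f + params.lapse / (2.0 * self.window)
        return float(np.sum(np.log(np.maximum(dens, floor))))


def dataset_loglik(trials: Sequence[Trial], params: DDMParams, condition: str,
                   variant: ModelVariant | None = None,
                   dt: float = 0.01, dx: float = 0.01,
                   drift_round: float = 0.005, start_round: float = 0.002
                   ) -> float:
    """Log-likelihood of a trial set under one parameter vector."""
    data = _LikelihoodData(trials, condition, dt=dt, dx=dx,
                           drift_round=drift_round, start_round=start_round)
    dv = variant is not None and "v_width" in variant.free_params
    return data.loglik(params, drift_variability=dv)


# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    subject_id: str
    variant: ModelVariant
    estimates: dict[str, float]
    loglik: float
    n_trials: int
    optimizer_meta: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.variant.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2.0 * self.loglik

    @property
    def params(self) -> DDMParams:
        return self.variant.build_params(
            [self.estimates[p] for p in self.variant.free_params])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "subject_id": self.subject_id,
                "variant": self.variant.name,
                "condition": self.variant.condition,
                "estimates": self.estimates,
                "loglik": self.loglik,
                "n_params": self.n_params,
                "aic": self.aic, "bic": self.bic,
                "n_trials": self.n_trials,
                "optimizer_meta": self.optimizer_meta,
            }, fh, indent=1)


#: default optimizer configuration (differential evolution, rand/1/bin,
#: followed by a bounded quasi-Newton polish on the unrounded likelihood)
DEFAULT_OPTIMIZER = dict(popsize=15, maxiter=300, mutation=0.7,
                         recombination=0.9, tol=1e-6,
                         init="latinhypercube", dt=0.01, dx=0.01,
                         drift_round=0.005, start_round=0.002,
                         polish=True, polish_maxiter=300, warm_start=True)

#: reduced-budget presets: a coarser solver grid and smaller DE population
#: for exploratory / simulation-study use (final polish still runs on the
#: unquantized likelihood at the same grid)
FAST_OPTIMIZER = {
    "rule": dict(popsize=8, maxiter=60, tol=1e-6, dt=0.02, dx=0.02,
                 drift_round=0.02, start_round=0.005, polish_maxiter=150),
    "stim": dict(popsize=8, maxiter=100, tol=1e-6, dt=0.02, dx=0.02,
                 drift_round=0.05, start_round=0.01, polish_maxiter=150),
}
FAST_OPTIMIZER["mixed"] = FAST_OPTIMIZER["stim"]


def fit_subject(trials: Sequence[Trial], variant: ModelVariant,
                optimizer_config: dict | None = None, seed: int = 0,
                subject_id: str | None = None) -> FitResult:
    """Differential-evolution ML fit of one variant to one subject's trials.

    The global stage evaluates a likelihood whose per-trial drivers are
    lightly quantized for solver reuse; the polish stage re-optimizes the
    exact likelihood with L-BFGS-B in box-normalized coordinates (finite
    differences sized above the solver's interpolation noise).

    ``optimizer_config`` overrides :data:`DEFAULT_OPTIMIZER` (popsize, maxiter,
    tol, solver dt/dx, ...).  Deterministic given ``seed``.  Non-convergence is
    flagged in ``optimizer_meta`` rather than raised.
    """
    cfg = dict(DEFAULT_OPTIMIZER)
    cfg.update(optimizer_config or {})
    dt, dx = cfg.pop("dt"), cfg.pop("dx")
    do_polish = cfg.pop("polish")
    polish_maxiter = cfg.pop("polish_maxiter")
    warm = cfg.pop("warm_start")
    data = _LikelihoodData(trials, variant.condition, dt=dt, dx=dx,
                           drift_round=cfg.pop("drift_round"),
                           start_round=cfg.pop("start_round"))
    dv = "v_width" in variant.free_params

    def nll(theta, lkd=data):
        try:
            params = variant.build_params(theta)
        except ValueError:
            return 1e12
        return -lkd.loglik(params, drift_variability=dv)

    # warm start: seed the population around a cheap no-history fit, which
    # pins the (v_snr, B, t_B, ndt_0) ridge before the bias terms open up
    init = cfg.pop("init")
    if warm and variant.name not in ("base", "collapsing"):
        anchor = "collapsing" if "t_B" in variant.free_params else "base"
        a_var = get_variant(variant.condition if variant.condition != "mixed"
                            else "rule", anchor)
        a_fit = fit_subject(trials, a_var,
                            dict(popsize=12, maxiter=80, tol=1e-6,
                                 warm_start=False, dt=dt, dx=dx),
                            seed=seed, subject_id=subject_id)
        rng = np.random.default_rng(seed + 1)
        dim = variant.n_params
        lo = np.array([b[0] for b in variant.bounds])
        hi = np.array([b[1] for b in variant.bounds])
        n_pop = max(cfg.get("popsize", 15) * dim, 5)
        pop = lo + (hi - lo) * rng.random((n_pop, dim))
        center = np.array([
            a_fit.estimates.get(p, 0.0 if lo[i] < 0 <= hi[i]
                                else 0.5 * (lo[i] + hi[i]))
            for i, p in enumerate(variant.free_params)])
        center = np.clip(center, lo, hi)
        for r in range(n_pop // 2):
            jitter = rng.normal(0.0, 0.05 * (hi - lo))
            pop[r] = np.clip(center + (0.0 if r == 0 else jitter), lo, hi)
        init = pop

    res = optimize.differential_evolution(
        nll, bounds=variant.bounds, seed=seed, strategy="rand1bin",
        updating="deferred", workers=1, polish=False, init=init, **cfg)
    best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
    n_eval = int(res.nfev)

    if do_polish:
        exact = _LikelihoodData(trials, variant.condition, dt=dt, dx=dx,
                                drift_round=1e-12, start_round=1e-12)
        lo = np.array([b[0] for b in variant.bounds])
        hi = np.array([b[1] for b in variant.bounds])
        span = hi - lo

        def nll_unit(u):
            return nll(lo + u * span, lkd=exact)

        u = (best_x - lo) / span
        fval = nll_unit(u)
        for eps in (1e-4, 1e-5):
            pr = optimize.minimize(
                nll_unit, u, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * u.size,
                options=dict(eps=eps, maxiter=polish_maxiter))
            n_eval += int(pr.nfev)
            if pr.fun < fval:
                u, fval = pr.x, float(pr.fun)
        best_x, best_f = lo + u * span, fval

    estimates = {p: float(v) for p, v in zip(variant.free_params, best_x)}
    sid = subject_id if subject_id is not None else trials[0].subject_id
    return FitResult(
        subject_id=sid, variant=variant, estimates=estimates,
        loglik=float(-best_f), n_trials=data.n,
        optimizer_meta={"seed": seed, "iterations": int(res.nit),
                        "n_evaluations": n_eval,
                        "converged": bool(res.success or do_polish)},
    )


def likelihood_ratio_test(full: FitResult, reduced: FitResult
                          ) -> tuple[float, int, float]:
    """chi2 = 2 (LL_full - LL_reduced), clipped at zero; upper-tail p.

    The clip absorbs small negative log-likelihood ratios arising from local
    minima near the global solution.
    """
    if not reduced.variant.is_nested_in(full.variant):
        raise ValueError("reduced variant is not nested in the full variant")
    if full.subject_id != reduced.subject_id or full.n_trials != reduced.n_trials:
        raise ValueError("LRT requires fits to the same subject and data")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def classify_subject(full: FitResult, evidence_only: FitResult,
                     start_only: FitResult, alpha: float = 0.05) -> str:
    """Label which bias mechanisms the data demand for one subject.

    Compares the full model against the evidence-only fit (tests the
    starting-point terms) and the starting-point-only fit (tests the
    evidence terms).
    """
    _, _, p_start_terms = likelihood_ratio_test(full, evidence_only)
    _, _, p_evidence_terms = likelihood_ratio_test(full, start_only)
    need_start = p_start_terms < alpha
    need_ev = p_evidence_terms < alpha
    if need_start and need_ev:
        return "both_needed"
    if need_ev:
        return "evidence_needed"
    if need_start:
        return "start_needed"
    return "neither"
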