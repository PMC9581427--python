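"""Logistic choice models and descriptive choice/RT statistics.

The psychometric model is P(H) = lambda + (1 - 2 lambda) / (1 + e^-f), a
logistic in signed SNR with a lapse rate setting both asymptotes.  Rule-based
fits free the offset (and optionally the slope) per prior cue; stimulus-based
fits add per-position pre-test-tone regressors (contrast coded +/- 0.5) and,
in the adaptation model, their interactions with unsigned SNR.  Positions are
numbered from 1 for the tone immediately before the test tone (the DDM's
exponential sums number the same tone 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task_design import Trial

__all__ = [
    "LogisticFit",
    "BiasSummary",
    "fit_logistic",
    "predict_choice_prob",
    "choice_bias",
    "chronometric_summary",
    "congruence_label",
    "bias_coupling",
]

_CUE_ORDER = ("low", "neutral", "high")
MODELS = ("base", "bias", "bias_sensitivity", "stim_bias", "stim_bias_adapt")


@dataclass
class LogisticFit:
    model: str
    lapse: float
    beta_snr: float | None = None
    beta_snr_by_cue: dict[str, float] | None = None
    beta0: float | None = None
    beta0_by_cue: dict[str, float] | None = None
    beta_pt: np.ndarray | None = None     # position 1..n_back
    beta_pta: np.ndarray | None = None    # adaptation interaction terms
    n_back: int = 0
    loglik: float = float("nan")
    n_trials: int = 0
    flagged: bool = False

    @property
    def n_params(self) -> int:
        n = 1  # lapse
        n += len(self.beta_snr_by_cue) if self.beta_snr_by_cue else 1
        n += len(self.beta0_by_cue) if self.beta0_by_cue else 1
        n += 0 if self.beta_pt is None else len(self.beta_pt)
        n += 0 if self.beta_pta is None else len(self.beta_pta)
        return n

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_trials) - 2 * self.loglik


def _pt_codes(trial: Trial, n_back: int) -> np.ndarray:
    """Contrast codes of the last ``n_back`` pre-test tones (+0.5 high,
    -0.5 low, 0 when the sequence is shorter); index 0 = position 1."""
    codes = np.zeros(n_back)
    for i in range(1, n_back + 1):
        if len(trial.pretest) >= i:
            codes[i - 1] = 0.5 if trial.pretest[-i] == "H" else -0.5
    return codes


def _linear_predictor(fit: LogisticFit, trial: Trial) -> float:
    if fit.model in ("base", "bias", "bias_sensitivity"):
        label = trial.cue.label if trial.cue is not None else "neutral"
        if fit.model == "base":
            return fit.beta0 + fit.beta_snr * trial.snr_unit
        b0 = fit.beta0_by_cue[label]
        bsnr = (fit.beta_snr_by_cue[label] if fit.model == "bias_sensitivity"
                else fit.beta_snr)
        return b0 + bsnr * trial.snr_unit
    if len(trial.pretest) == 0:
        raise ValueError("stimulus-based fit requires a pre-test sequence")
    codes = _pt_codes(trial, fit.n_back)
    f = fit.beta0 + fit.beta_snr * trial.snr_unit + float(codes @ fit.beta_pt)
    if fit.beta_pta is not None:
        f += float(codes @ fit.beta_pta) * abs(trial.snr_unit)
    return f


def predict_choice_prob(fit: LogisticFit, trial: Trial) -> float:
    """P(choose high frequency) for one trial under a fitted model."""
    f = _linear_predictor(fit, trial)
    lam = fit.lapse
    return lam + (1.0 - 2.0 * lam) / (1.0 + math.exp(-f))


def _design(trials: Sequence[Trial], model: str, n_back: int
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (excluding lapse) and response vector y = 1{choice H}."""
    y = np.array([t.choice == "H" for t in trials], dtype=float)
    snr = np.array([t.snr_unit for t in trials])
    cols: list[np.ndarray] = []
    names: list[str] = []
    if model == "base":
        cols += [np.ones_like(snr), snr]
        names += ["beta0", "beta_snr"]
    elif model in ("bias", "bias_sensitivity"):
        labels = np.array([t.cue.label if t.cue else "neutral" for t in trials])
        for c in _CUE_ORDER:
            cols.append((labels == c).astype(float))
            names.append(f"beta0_{c}")
        if model == "bias":
            cols.append(snr)
            names.append("beta_snr")
        else:
            for c in _CUE_ORDER:
                cols.append(snr * (labels == c))
                names.append(f"beta_snr_{c}")
    else:
        codes = np.array([_pt_codes(t, n_back) for t in trials])
        cols += [np.ones_like(snr), snr]
        names += ["beta0", "beta_snr"]
        for i in range(n_back):
            cols.append(codes[:, i])
            names.append(f"beta_pt{i + 1}")
        if model == "stim_bias_adapt":
            for i in range(n_back):
                cols.append(codes[:, i] * np.abs(snr))
                names.append(f"beta_pta{i + 1}")
    return np.column_stack(cols), y, names


def fit_logistic(trials: Sequence[Trial], model: str = "bias",
                 n_back: int = 2, seed: int = 0, n_starts: int = 10,
                 lapse_max: float = 0.2) -> LogisticFit:
    """Maximum-likelihood logistic fit with a shared lapse rate.

    Multi-start quasi-Newton (L-BFGS-B) on the negative log-likelihood;
    coefficient magnitudes are capped at 50 so complete separation yields a
    flagged, clamped fit instead of a divergence.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if n_back > 6:
        raise ValueError("n_back must be <= 6")
    trials = [t for t in trials if t.choice in ("L", "H")]
    if len(trials) < 50:
        raise ValueError("need >= 50 responded trials")
    X, y, names = _design(trials, model, n_back)
    nb = X.shape[1]

    def nll(theta):
        lam = theta[0]
        f = X @ theta[1:]
        p = lam + (1.0 - 2.0 * lam) / (1.0 + np.exp(-f))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    bounds = [(0.0, lapse_max)] + [(-50.0, 50.0)] * nb
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.concatenate([[rng.uniform(0, lapse_max / 2)],
                             rng.normal(0, 1.0, nb)])
        if s == 0:
            x0 = np.concatenate([[0.02], np.zeros(nb)])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    coefs = dict(zip(names, theta[1:]))
    flagged = bool(np.any(np.abs(theta[1:]) >= 49.9))
    fit = LogisticFit(model=model, lapse=float(theta[0]),
                      loglik=float(-best.fun), n_trials=len(trials),
                      n_back=n_back if model.startswith("stim") else 0,
                      flagged=flagged)
    if model == "base":
        fit.beta0 = coefs["beta0"]
        fit.beta_snr = coefs["beta_snr"]
    elif model == "bias":
        fit.beta0_by_cue = {c: coefs[f"beta0_{c}"] for c in _CUE_ORDER}
        fit.beta_snr = coefs["beta_snr"]
    elif model == "bias_sensitivity":
        fit.beta0_by_cue = {c: coefs[f"beta0_{c}"] for c in _CUE_ORDER}
        fit.beta_snr_by_cue = {c: coefs[f"beta_snr_{c}"] for c in _CUE_ORDER}
    else:
        fit.beta0 = coefs["beta0"]
        fit.beta_snr = coefs["beta_snr"]
        fit.beta_pt = np.array([coefs[f"beta_pt{i+1}"] for i in range(n_back)])
        if model == "stim_bias_adapt":
            fit.beta_pta = np.array([coefs[f"beta_pta{i+1}"]
                                     for i in range(n_back)])
    return fit


def choice_bias(fit: LogisticFit) -> float:
    """Behavioral bias magnitude: beta0_High - beta0_Low from a rule fit."""
    if not fit.beta0_by_cue:
        raise ValueError("choice_bias needs a per-cue (rule-based) fit")
    return fit.beta0_by_cue["high"] - fit.beta0_by_cue["low"]


# ---------------------------------------------------------------------------
# descriptive summaries

def congruence_label(trial: Trial, with_respect_to: str = "choice") -> str | None:
    """Congruence of the expectation cue with the choice (or the tone).

    Rule/mixed trials: congruent when the cue's more-probable frequency
    matches; neutral cues map to "neutral".  Stimulus-based trials: defined
    only when the last two pre-test tones agree (HH or LL); otherwise None.
    """
    target = trial.choice if with_respect_to == "choice" else trial.tone
    if target == "none":
        return None
    if trial.cue is not None:
        if trial.cue.label == "neutral":
            return "neutral"
        favored = "H" if trial.cue.label == "high" else "L"
        return "congruent" if target == favored else "incongruent"
    if len(trial.pretest) >= 2 and trial.pretest[-1] == trial.pretest[-2]:
        return "congruent" if target == trial.pretest[-1] else "incongruent"
    return None


def chronometric_summary(trials: Sequence[Trial],
                         with_respect_to: str = "choice") -> pd.DataFrame:
    """Median correct RT per congruence x |SNR| cell.

    Per-subject medians first, then across-subject means; cells with no
    trials in some subject are flagged via the ``n_subjects`` column.
    """
    rows = []
    for t in trials:
        if not t.correct or t.choice == "none":
            continue
        lab = congruence_label(t, with_respect_to)
        if lab is None:
            continue
        rows.append((t.subject_id, lab, abs(t.snr_unit), t.rt))
    if not rows:
        return pd.DataFrame(columns=["congruence", "abs_snr", "median_rt_s",
                                     "n_subjects"])
    df = pd.DataFrame(rows, columns=["subject", "congruence", "abs_snr", "rt"])
    per_subj = (df.groupby(["subject", "congruence", "abs_snr"])["rt"]
                  .median().rename("median_rt_s").reset_index())
    out = (per_subj.groupby(["congruence", "abs_snr"])["median_rt_s"]
           .agg(["mean", "count"]).reset_index()
           .rename(columns={"mean": "median_rt_s", "count": "n_subjects"}))
    return out


@dataclass
class BiasSummary:
    context: str
    z_biases: np.ndarray
    v_biases: np.ndarray
    coupling_rho: float
    rho_p: float
    slope_v_on_z: float
    slope_z_on_v: float
    flagged: bool = False


def bias_coupling(z_biases: Sequence[float], v_biases: Sequence[float],
                  context: str = "") -> BiasSummary:
    """Across-subject coupling of starting-point and evidence biases.

    Spearman rho plus least-squares slopes between the z-scored biases in
    both orientations.  Constant inputs yield a flagged, NaN summary.
    """
    z = np.asarray(z_biases, dtype=float)
    v = np.asarray(v_biases, dtype=float)
    if z.shape != v.shape or z.size < 10:
        raise ValueError("need matched bias vectors with >= 10 subjects")
    if np.std(z) == 0 or np.std(v) == 0:
        return BiasSummary(context, z, v, float("nan"), float("nan"),
                           float("nan"), float("nan"), flagged=True)
    rho, p = stats.spearmanr(z, v)
    zs = (z - z.mean()) / z.std()
    vs = (v - v.mean()) / v.std()
    slope_v_on_z = float(np.polyfit(zs, vs, 1)[0])
    slope_z_on_v = float(np.polyfit(vs, zs, 1)[0])
    return BiasSummary(context, z, v, float(rho), float(p),
                       slope_v_on_z, slope_z_on_v)
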