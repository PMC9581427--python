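"""Cohort-level model comparison.

Information-criterion aggregation plus random-effects Bayesian model
selection: a variational Dirichlet posterior over population model
frequencies, exceedance probabilities by Monte-Carlo integration, and the
Bayes omnibus risk (BOR) that protects them against the chance that all
models are equally frequent:

    PEP_k = EP_k * (1 - BOR) + BOR / K

Model evidence is approximated as -AIC/2 when fits are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult

__all__ = ["ComparisonTable", "information_criteria", "rfx_bms",
           "evidence_matrix"]


@dataclass
class ComparisonTable:
    variants: list[str]
    mean_aic: np.ndarray | None = None
    mean_bic: np.ndarray | None = None
    expected_freq: np.ndarray | None = None
    exceedance: np.ndarray | None = None
    pep: np.ndarray | None = None
    bor: float | None = None
    alpha: np.ndarray | None = None

    def delta_aic(self, a: str, b: str) -> float:
        """Mean over subjects of AIC_a - AIC_b (negative favours a)."""
        ia, ib = self.variants.index(a), self.variants.index(b)
        return float(self.mean_aic[ia] - self.mean_aic[ib])

    def to_frame(self) -> pd.DataFrame:
        cols = {"model": self.variants}
        if self.mean_aic is not None:
            cols["mean AIC"] = self.mean_aic
        if self.pep is not None:
            cols["PEP"] = self.pep
        if self.mean_bic is not None:
            cols["mean BIC"] = self.mean_bic
        return pd.DataFrame(cols)


def _fit_grid(fits: Mapping[str, Mapping[str, FitResult]],
              attr: str) -> tuple[list[str], list[str], np.ndarray]:
    """fits[subject][variant] -> (subjects, variants, matrix of ``attr``)."""
    subjects = sorted(fits)
    variants = sorted({v for d in fits.values() for v in d})
    missing = [(s, v) for s in subjects for v in variants if v not in fits[s]]
    if missing:
        raise ValueError(f"incomplete fit grid; missing cells: {missing}")
    mat = np.array([[getattr(fits[s][v], attr) for v in variants]
                    for s in subjects])
    return subjects, variants, mat


def information_criteria(fits: Mapping[str, Mapping[str, FitResult]]
                         ) -> ComparisonTable:
    """Across-subject mean AIC and BIC per variant from a complete fit grid."""
    _, variants, aic = _fit_grid(fits, "aic")
    _, _, bic = _fit_grid(fits, "bic")
    return ComparisonTable(variants=variants, mean_aic=aic.mean(axis=0),
                           mean_bic=bic.mean(axis=0))


def evidence_matrix(fits: Mapping[str, Mapping[str, FitResult]]
                    ) -> tuple[list[str], np.ndarray]:
    """Per-subject log model evidences approximated as -AIC/2."""
    _, variants, aic = _fit_grid(fits, "aic")
    return variants, -aic / 2.0


def _vb_dirichlet(log_ev: np.ndarray, alpha0: float, tol: float,
                  max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Variational posterior over model frequencies.

    Returns (alpha, responsibilities u, free energy F1).
    """
    n, K = log_ev.shape
    alpha = np.full(K, alpha0)
    u = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        log_u = log_ev + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    # variational free energy of the random-effects model
    dg = digamma(alpha) - digamma(alpha.sum())
    a0 = np.full(K, alpha0)
    ln_b = gammaln(alpha).sum() - gammaln(alpha.sum())
    ln_b0 = gammaln(a0).sum() - gammaln(a0.sum())
    F1 = (np.sum(u * log_ev) + np.sum(u * dg)
          - np.sum(u * np.log(np.maximum(u, 1e-300)))
          + np.sum((a0 - alpha) * dg) + ln_b - ln_b0)
    return alpha, u, float(F1)


def rfx_bms(log_evidence: np.ndarray, alpha0: float = 1.0,
            n_samples: int = 100_000, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 500,
            variants: Sequence[str] | None = None) -> ComparisonTable:
    """Random-effects Bayesian model selection over a subjects x variants
    matrix of log evidences.

    Expected model frequencies come from the variational Dirichlet posterior;
    exceedance probabilities from ``n_samples`` seeded Dirichlet draws; the
    protected exceedance probability blends the exceedance probability with
    uniform 1/K in proportion to the Bayes omnibus risk.
    """
    log_ev = np.asarray(log_evidence, dtype=float)
    if log_ev.ndim != 2 or log_ev.shape[0] < 2 or log_ev.shape[1] < 2:
        raise ValueError("need a subjects x variants matrix with >= 2 of each")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")
    n, K = log_ev.shape
    # per-subject normalization (invariant for the model, numerically safer)
    log_ev = log_ev - logsumexp(log_ev, axis=1, keepdims=True)

    alpha, u, F1 = _vb_dirichlet(log_ev, alpha0, tol, max_iter)
    expected_freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=K) / n_samples

    # null model: every subject draws models with equal frequency 1/K
    F0 = float(np.sum(logsumexp(log_ev, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pep = ep * (1.0 - bor) + bor / K

    names = list(variants) if variants is not None else \
        [f"m{k}" for k in range(K)]
    return ComparisonTable(variants=names, expected_freq=expected_freq,
                           exceedance=ep, pep=pep, bor=bor, alpha=alpha)
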