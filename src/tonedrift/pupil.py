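"""Pupillometry pipeline: cleaning, epoching, time-course contrasts.

Continuous 1000-Hz pupil/gaze recordings are cleaned (blink and
high-velocity artifacts removed with a +/-100 ms guard band and linearly
interpolated, then low-pass filtered at 8 Hz), z-scored within block,
epoched around the choice with a 0-40 ms post-tone-onset baseline
subtracted, screened by missing-data and fixation criteria, and downsampled
to 50 Hz.  Group statistics use a two-stage scheme: per-subject ordinary
least squares in every 20-ms bin with nuisance covariates, then one-sample
tests across subjects with Benjamini-Hochberg correction across bins and
contrasts jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PupilRecording",
    "EpochedPupil",
    "clean_trace",
    "epoch_and_exclude",
    "timecourse_contrasts",
    "bias_pupil_correlation",
]

FS = 1000  # Hz
VELOCITY_THRESHOLD = 24.0   # a.u. per ms
VELOCITY_LONG_MS = 16       # velocity runs longer than this get the guard band
GUARD_MS = 100
FILTER_CUTOFF_HZ = 8.0
FILTER_ORDER = 3


@dataclass
class PupilRecording:
    """One block of continuous eye data at 1000 Hz."""

    t_ms: np.ndarray
    diameter: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    missing_mask: np.ndarray
    events: pd.DataFrame  # columns: trial_index, tone_onset_ms, choice_ms
    block_id: int = 0
    interp_mask: np.ndarray | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms)
        if t.size > 1 and not np.all(np.diff(t) == 1):
            raise ValueError("recording must be uniformly sampled at 1 ms")
        for col in ("tone_onset_ms", "choice_ms"):
            ev = self.events[col].to_numpy()
            if np.any((ev < t[0]) | (ev > t[-1])):
                raise ValueError(f"{col} outside recording span")


@dataclass
class EpochedPupil:
    """Choice-aligned, baseline-corrected trial time courses (z units)."""

    subject_id: str
    times_ms: np.ndarray            # relative to choice, 1 ms step
    traces: np.ndarray              # (n_trials, n_times)
    baselines: np.ndarray
    interp_frac: np.ndarray
    trial_index: np.ndarray
    excluded: np.ndarray            # bool
    exclusion_reason: np.ndarray    # "" | missing_data | gaze | session
    zero_variance_flag: bool = False
    bin_ms: int = 20

    @property
    def bin_times_ms(self) -> np.ndarray:
        n_bins = self.times_ms.size // self.bin_ms
        t = self.times_ms[:n_bins * self.bin_ms].reshape(n_bins, self.bin_ms)
        return t.mean(axis=1)

    def downsampled(self) -> np.ndarray:
        """50-Hz copy: mean over consecutive 20-ms bins."""
        n_bins = self.times_ms.size // self.bin_ms
        x = self.traces[:, :n_bins * self.bin_ms]
        return x.reshape(x.shape[0], n_bins, self.bin_ms).mean(axis=2)

    def included(self) -> np.ndarray:
        return ~self.excluded


# ---------------------------------------------------------------------------
# cleaning

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _interpolate_spans(x: np.ndarray, bad: np.ndarray) -> tuple[np.ndarray, bool]:
    """Linear interpolation over bad samples; edges use nearest-value
    extension.  Returns (filled, edge_flag)."""
    good = ~bad
    edge = bad[0] or bad[-1]
    if good.sum() == 0:
        return x.copy(), True
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out, bool(edge)


def clean_trace(rec: PupilRecording) -> PupilRecording:
    """Artifact removal, interpolation and 8-Hz low-pass filtering.

    Blink/missing gaps are expanded by +/-100 ms.  High-velocity samples
    (|first difference| > 24 a.u./ms) are removed; runs longer than 16 ms
    also receive the +/-100 ms guard band.  Gaze is interpolated over the
    same spans.  Already-cleaned recordings pass through unchanged, making
    the operation idempotent.
    """
    if rec.filtered:
        return rec
    n = rec.diameter.size
    guard = GUARD_MS

    bad = np.zeros(n, dtype=bool)
    for s, e in _runs(np.asarray(rec.missing_mask, dtype=bool)):
        bad[max(0, s - guard):min(n, e + guard)] = True

    vel = np.abs(np.diff(rec.diameter, prepend=rec.diameter[0]))
    vel_mask = vel > VELOCITY_THRESHOLD
    for s, e in _runs(vel_mask):
        if e - s > VELOCITY_LONG_MS:
            bad[max(0, s - guard):min(n, e + guard)] = True
        else:
            bad[s:e] = True

    diam, edge = _interpolate_spans(rec.diameter, bad)
    gx, _ = _interpolate_spans(rec.gaze_x, bad)
    gy, _ = _interpolate_spans(rec.gaze_y, bad)

    sos = signal.butter(FILTER_ORDER, FILTER_CUTOFF_HZ, btype="low",
                        fs=FS, output="sos")
    diam = signal.sosfiltfilt(sos, diam)

    return replace(rec, diameter=diam, gaze_x=gx, gaze_y=gy,
                   missing_mask=np.zeros(n, dtype=bool),
                   interp_mask=bad, filtered=True)


# ---------------------------------------------------------------------------
# epoching and exclusion

def epoch_and_exclude(
    cleaned: Sequence[PupilRecording] | PupilRecording,
    subject_id: str = "S00",
    epoch_ms: tuple[int, int] = (-500, 1500),
    baseline_ms: tuple[int, int] = (0, 40),
    fixation_radius: float | None = None,
    trial_missing_max: float = 0.5,
    session_missing_max: float = 0.6,
    gaze_excursion_ms: int = 15,
    min_trials: int = 75,
) -> tuple[EpochedPupil, dict]:
    """Build choice-aligned epochs and apply the exclusion cascade.

    Per trial: >50% interpolated samples -> "missing_data"; continuous gaze
    excursion beyond the fixation circle for more than 15 ms -> "gaze".
    Whole recordings with >60% interpolated data exclude all of their trials
    ("session").  The report notes whether the subject falls below the
    75-trial survival threshold.  The fixation circle defaults to the 95th
    percentile of baseline-centered gaze radii across the session.
    """
    recs = [cleaned] if isinstance(cleaned, PupilRecording) else list(cleaned)
    for r in recs:
        if not r.filtered:
            raise ValueError("run clean_trace before epoching")

    lo, hi = epoch_ms
    times = np.arange(lo, hi)
    traces, baselines, fracs, tix, reasons = [], [], [], [], []
    zero_var = False
    radii_all: list[np.ndarray] = []

    per_trial_gaze = []  # (centered gx, gy) per trial for the radius rule
    for rec in recs:
        # z-score within block (zero-variance guarded to zeros)
        sd = rec.diameter.std()
        if sd <= 1e-8 * (1.0 + abs(float(rec.diameter.mean()))):
            z = np.zeros_like(rec.diameter)
            zero_var = True
        else:
            z = (rec.diameter - rec.diameter.mean()) / sd
        session_bad = rec.interp_mask is not None and \
            rec.interp_mask.mean() > session_missing_max
        t0 = int(rec.t_ms[0])
        for ev in rec.events.itertuples(index=False):
            onset = int(ev.tone_onset_ms) - t0
            choice = int(ev.choice_ms) - t0
            b0, b1 = onset + baseline_ms[0], onset + baseline_ms[1]
            s, e = choice + lo, choice + hi
            tr = np.full(times.size, np.nan)
            src0, src1 = max(0, s), min(z.size, e)
            tr[src0 - s:src0 - s + (src1 - src0)] = z[src0:src1]
            base = float(np.mean(z[b0:b1])) if 0 <= b0 < b1 <= z.size else 0.0
            tr -= base
            interp = (rec.interp_mask[src0:src1]
                      if rec.interp_mask is not None else np.zeros(src1 - src0))
            frac = float(np.mean(interp)) if src1 > src0 else 1.0

            gx = rec.gaze_x[src0:src1] - float(np.mean(rec.gaze_x[b0:b1]))
            gy = rec.gaze_y[src0:src1] - float(np.mean(rec.gaze_y[b0:b1]))
            r = np.hypot(gx, gy)
            radii_all.append(r)
            per_trial_gaze.append(r)

            traces.append(tr)
            baselines.append(base)
            fracs.append(frac)
            tix.append(int(ev.trial_index))
            reasons.append("session" if session_bad else "")

    fracs = np.array(fracs)
    reasons = np.array(reasons, dtype=object)
    free = reasons == ""
    reasons[free & (fracs > trial_missing_max)] = "missing_data"

    if fixation_radius is None:
        allr = np.concatenate(radii_all) if radii_all else np.array([0.0])
        fixation_radius = float(np.percentile(allr, 95))
    for i, r in enumerate(per_trial_gaze):
        if reasons[i]:
            continue
        out = r > fixation_radius
        if out.any() and max(e - s for s, e in _runs(out)) > gaze_excursion_ms:
            reasons[i] = "gaze"

    excluded = reasons != ""
    epochs = EpochedPupil(
        subject_id=subject_id, times_ms=times,
        traces=np.array(traces), baselines=np.array(baselines),
        interp_frac=fracs, trial_index=np.array(tix),
        excluded=excluded, exclusion_reason=reasons,
        zero_variance_flag=zero_var,
    )
    n_kept = int((~excluded).sum())
    report = {
        "n_trials": int(excluded.size),
        "n_kept": n_kept,
        "n_missing_data": int((reasons == "missing_data").sum()),
        "n_gaze": int((reasons == "gaze").sum()),
        "n_session": int((reasons == "session").sum()),
        "fixation_radius": fixation_radius,
        "subject_excluded": n_kept < min_trials,
        "min_trials": min_trials,
    }
    return epochs, report


# ---------------------------------------------------------------------------
# statistics

def _subject_betas(pupil_bins: np.ndarray, design: pd.DataFrame,
                   contrast_cols: list[str], covariate_cols: list[str]
                   ) -> np.ndarray:
    """OLS per bin; returns (n_contrasts, n_bins) with collinear covariates
    dropped when the design is rank deficient."""
    cols = contrast_cols + covariate_cols
    X = np.column_stack([np.ones(len(design))] +
                        [design[c].to_numpy(dtype=float) for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep = [0] + [1 + i for i in range(len(contrast_cols))]
        Xr = X[:, keep]
        for j in range(len(contrast_cols) + 1, X.shape[1]):
            trial = np.column_stack([Xr, X[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                Xr = trial
        X = Xr
    beta, *_ = np.linalg.lstsq(X, pupil_bins, rcond=None)
    return beta[1:1 + len(contrast_cols), :]


def timecourse_contrasts(
    data: pd.DataFrame, pupil_bins: np.ndarray,
    contrast_cols: list[str], covariate_cols: list[str] | None = None,
    bin_times_ms: np.ndarray | None = None, fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Two-stage per-bin contrast estimates with FDR-adjusted p values.

    ``data`` holds one row per trial (all subjects stacked) with a
    ``subject`` column, contrast codes and covariates; ``pupil_bins`` is the
    matching (n_trials, n_bins) matrix of 20-ms binned pupil values.  Stage
    one fits OLS per subject and bin; stage two runs a one-sample t test
    across subjects per bin and contrast, with Benjamini-Hochberg adjustment
    jointly across bins and contrasts.
    """
    covariate_cols = covariate_cols or []
    subjects = data["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects for the group stage")
    n_bins = pupil_bins.shape[1]
    betas = np.full((len(subjects), len(contrast_cols), n_bins), np.nan)
    for i, s in enumerate(subjects):
        m = (data["subject"] == s).to_numpy()
        betas[i] = _subject_betas(pupil_bins[m], data.loc[m],
                                  contrast_cols, covariate_cols)

    rows = []
    for c, name in enumerate(contrast_cols):
        b = betas[:, c, :]
        mean = b.mean(axis=0)
        se = b.std(axis=0, ddof=1) / np.sqrt(b.shape[0])
        tstat = np.divide(mean, se, out=np.zeros_like(mean), where=se > 0)
        p = 2 * stats.t.sf(np.abs(tstat), df=b.shape[0] - 1)
        for j in range(n_bins):
            rows.append((name,
                         float(bin_times_ms[j]) if bin_times_ms is not None
                         else float(j),
                         mean[j], se[j], tstat[j], p[j]))
    out = pd.DataFrame(rows, columns=["contrast", "bin_ms", "beta", "se",
                                      "t", "p"])
    _, p_adj, *_ = multipletests(out["p"].to_numpy(), alpha=fdr_q,
                                 method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = out["p_fdr"] < fdr_q
    return out


def bias_pupil_correlation(choice_bias: Sequence[float],
                           contrast_betas: np.ndarray,
                           bin_times_ms: np.ndarray | None = None,
                           fdr_q: float = 0.05) -> pd.DataFrame:
    """Across-subject Spearman correlation of behavioral bias with the
    per-subject pupil contrast, per 20-ms bin, BH-adjusted across bins."""
    bias = np.asarray(choice_bias, dtype=float)
    betas = np.asarray(contrast_betas, dtype=float)
    if bias.size < 10:
        raise ValueError("need >= 10 subjects")
    if betas.shape[0] != bias.size:
        raise ValueError("contrast_betas must be (n_subjects, n_bins)")
    rho = np.empty(betas.shape[1])
    p = np.empty(betas.shape[1])
    for j in range(betas.shape[1]):
        rho[j], p[j] = stats.spearmanr(bias, betas[:, j])
    _, p_adj, *_ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return pd.DataFrame({
        "bin_ms": bin_times_ms if bin_times_ms is not None
        else np.arange(betas.shape[1], dtype=float),
        "rho": rho, "p": p, "p_fdr": p_adj,
        "significant": p_adj < fdr_q,
    })
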