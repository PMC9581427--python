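"""Trial and session structure for the auditory frequency-discrimination task.

The task asks subjects to report whether a faint test tone embedded in broadband
noise is low or high frequency.  Expectations are manipulated either by a visual
prior cue (rule-based sessions: 576 trials in twelve 48-trial mini-blocks with
5:1, 1:1 or 1:5 high:low odds) or by a 2-14 tone "pre-test" sequence that
precedes the test tone (stimulus-based sessions: 480 trials, on average
non-predictive).  Mixed sessions combine both cue types.

This module owns the shared trial schema used by both the synthetic generator
and the analysis code, the dB -> unit SNR mapping, and the pre-test sequence
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CueCondition",
    "CUE_LOW",
    "CUE_NEUTRAL",
    "CUE_HIGH",
    "CUES",
    "SessionDesign",
    "Trial",
    "SNR_DB_LEVELS",
    "SNR_DB_RANGE",
    "SNR_UNIT_RANGE",
    "map_snr",
    "sample_pretest_sequence",
    "generate_session",
    "filter_analyzable",
    "trials_to_frame",
    "frame_to_trials",
    "read_trials",
    "write_trials",
]

Tone = Literal["L", "H"]

#: dB SNR of the test tone relative to the noise, lowest to highest level.
SNR_DB_LEVELS: tuple[float, ...] = (-23.0, -18.0, -13.0, -6.0)
SNR_DB_RANGE: tuple[float, float] = (-23.0, -6.0)
#: unsigned unit-SNR scale the dB range maps onto.
SNR_UNIT_RANGE: tuple[float, float] = (0.05, 0.5)


@dataclass(frozen=True)
class CueCondition:
    """A rule-based prior cue: the advertised odds that the test tone is high."""

    label: Literal["low", "neutral", "high"]
    p_high: float

    def __post_init__(self) -> None:
        if self.p_high not in (1.0 / 6.0, 0.5, 5.0 / 6.0):
            raise ValueError(f"p_high must be one of 1/6, 1/2, 5/6, got {self.p_high}")

    @property
    def odds_high_to_low(self) -> tuple[int, int]:
        return {1.0 / 6.0: (1, 5), 0.5: (1, 1), 5.0 / 6.0: (5, 1)}[self.p_high]


CUE_LOW = CueCondition("low", 1.0 / 6.0)
CUE_NEUTRAL = CueCondition("neutral", 0.5)
CUE_HIGH = CueCondition("high", 5.0 / 6.0)
CUES: dict[str, CueCondition] = {c.label: c for c in (CUE_LOW, CUE_NEUTRAL, CUE_HIGH)}


@dataclass(frozen=True)
class Trial:
    subject_id: str
    session_type: Literal["rule", "stim", "mixed1", "mixed2"]
    trial_index: int
    tone: Tone
    snr_db: float
    snr_unit: float
    block: int = 0
    cue: CueCondition | None = None
    pretest: tuple[Tone, ...] = ()  # chronological order; last element precedes the test tone
    choice: Literal["L", "H", "none"] = "none"
    rt: float = float("nan")  # seconds from go cue
    correct: bool = False
    response_window: float = 2.0

    def __post_init__(self) -> None:
        if self.tone not in ("L", "H"):
            raise ValueError(f"tone must be 'L' or 'H', got {self.tone!r}")
        want = 1.0 if self.tone == "H" else -1.0
        if self.snr_unit != 0 and np.sign(self.snr_unit) != want:
            raise ValueError("sign of snr_unit must match tone identity")
        if self.choice != "none" and not (0.0 < self.rt <= self.response_window):
            raise ValueError("rt must lie in (0, response_window] for responded trials")
        if self.session_type == "mixed2" and self.pretest and len(self.pretest) != 5:
            raise ValueError("mixed2 trials use pre-test sequences of exactly 5 tones")


@dataclass(frozen=True)
class SessionDesign:
    """Static description of one session's trial structure."""

    session_type: Literal["rule", "stim", "mixed1", "mixed2"]
    n_trials: int
    miniblock_len: int = 48
    pretest_length_range: tuple[int, int] = (2, 14)
    n_no_pretest: int = 38
    response_window: float = 2.0
    #: geometric success probability for pre-test sequence lengths (see methods note)
    pretest_geom_p: float = 0.45
    mixed1_cue: Literal["low", "high"] = "high"

    def __post_init__(self) -> None:
        if self.session_type in ("rule", "mixed2"):
            if self.n_trials % self.miniblock_len:
                raise ValueError("rule-style sessions need n_trials divisible by miniblock_len")
        lo, hi = self.pretest_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pretest_length_range")

    @classmethod
    def default(cls, session_type: str, **kw) -> "SessionDesign":
        base = {
            "rule": dict(n_trials=576, n_no_pretest=0),
            "stim": dict(n_trials=480, n_no_pretest=38),
            "mixed1": dict(n_trials=480, n_no_pretest=38),
            "mixed2": dict(n_trials=576, n_no_pretest=0,
                           pretest_length_range=(5, 5)),
        }[session_type]
        base.update(kw)
        return cls(session_type=session_type, **base)


def map_snr(snr_db: float, tone: Tone) -> float:
    """Map a dB SNR onto the signed unit scale used by the models.

    The unsigned value rescales dB linearly from [-23, -6] onto [0.05, 0.5];
    the sign encodes tone identity (high frequency positive).
    """
    lo_db, hi_db = SNR_DB_RANGE
    if not (lo_db <= snr_db <= hi_db):
        raise ValueError(f"snr_db {snr_db} outside [{lo_db}, {hi_db}]")
    lo_u, hi_u = SNR_UNIT_RANGE
    unsigned = lo_u + (snr_db - lo_db) / (hi_db - lo_db) * (hi_u - lo_u)
    return unsigned if tone == "H" else -unsigned


def sample_pretest_sequence(
    rng: np.random.Generator,
    min_len: int = 2,
    max_len: int = 14,
    geom_p: float = 0.45,
) -> tuple[Tone, ...]:
    """Draw one pre-test tone sequence.

    Length follows a geometric distribution (success probability ``geom_p``)
    truncated to [min_len, max_len], approximating the roughly exponential
    length distribution of the task; tone identities are i.i.d. fair draws
    (session-level balance is enforced by :func:`generate_session`).
    """
    if min_len == max_len:
        n = min_len
    else:
        lengths = np.arange(min_len, max_len + 1)
        pmf = geom_p * (1.0 - geom_p) ** (lengths - min_len)
        pmf /= pmf.sum()
        n = int(rng.choice(lengths, p=pmf))
    return tuple("H" if b else "L" for b in rng.integers(0, 2, size=n))


def _sample_balanced_pretests(
    rng: np.random.Generator, n_seq: int, design: SessionDesign,
    tol: float = 0.02, max_rounds: int = 100,
) -> list[tuple[Tone, ...]]:
    """Sample pre-test sequences, resampling until the session-level proportion
    of high tones is within ``tol`` of one half (capped at ``max_rounds``)."""
    lo, hi = design.pretest_length_range
    for _ in range(max_rounds):
        seqs = [sample_pretest_sequence(rng, lo, hi, design.pretest_geom_p)
                for _ in range(n_seq)]
        tones = [t for s in seqs for t in s]
        if tones and abs(sum(t == "H" for t in tones) / len(tones) - 0.5) <= tol:
            return seqs
    return seqs  # last attempt; caller documents best-effort balance


def generate_session(
    design: SessionDesign, rng: np.random.Generator, subject_id: str = "S00"
) -> list[Trial]:
    """Generate one session's worth of stimuli (responses unset).

    Rule sessions contain ``n_trials`` in constant-cue mini-blocks with the
    three cues counterbalanced (equal block counts, shuffled order).  Stimulus
    sessions draw the test tone with p(high) = 1/2 and attach a pre-test
    sequence to all but ``n_no_pretest`` trials, placed uniformly at random.
    """
    st = design.session_type
    trials: list[Trial] = []
    snr_levels = np.array(SNR_DB_LEVELS)

    def draw_tone(p_high: float) -> Tone:
        return "H" if rng.random() < p_high else "L"

    def stim_fields(i: int) -> tuple[Tone, float, float]:
        tone = draw_tone(p_highs[i])
        snr_db = float(rng.choice(snr_levels))
        return tone, snr_db, map_snr(snr_db, tone)

    if st in ("rule", "mixed2"):
        n_blocks = design.n_trials // design.miniblock_len
        if n_blocks % 3:
            raise ValueError("number of mini-blocks must be divisible by 3 for counterbalancing")
        if st == "rule":
            block_cues = np.repeat(["low", "neutral", "high"], n_blocks // 3)
            rng.shuffle(block_cues)
            cue_of_trial = np.repeat(block_cues, design.miniblock_len)
        else:  # mixed2: trial-wise cue, counterbalanced within session
            cue_of_trial = np.repeat(["low", "neutral", "high"], design.n_trials // 3)
            rng.shuffle(cue_of_trial)
        cues = [CUES[c] for c in cue_of_trial]
        p_highs = [c.p_high for c in cues]
        if st == "mixed2":
            pretests = _sample_balanced_pretests(rng, design.n_trials, design)
        for i in range(design.n_trials):
            tone, snr_db, snr_unit = stim_fields(i)
            trials.append(Trial(
                subject_id=subject_id, session_type=st, trial_index=i,
                block=i // design.miniblock_len, cue=cues[i],
                pretest=pretests[i] if st == "mixed2" else (),
                tone=tone, snr_db=snr_db, snr_unit=snr_unit,
                response_window=design.response_window,
            ))
    elif st in ("stim", "mixed1"):
        cue = CUES[design.mixed1_cue] if st == "mixed1" else None
        p_highs = [cue.p_high if cue else 0.5] * design.n_trials
        no_pre = set(rng.choice(design.n_trials, size=design.n_no_pretest,
                                replace=False).tolist())
        n_with = design.n_trials - design.n_no_pretest
        seqs = iter(_sample_balanced_pretests(rng, n_with, design))
        for i in range(design.n_trials):
            tone, snr_db, snr_unit = stim_fields(i)
            trials.append(Trial(
                subject_id=subject_id, session_type=st, trial_index=i,
                cue=cue, pretest=() if i in no_pre else next(seqs),
                tone=tone, snr_db=snr_db, snr_unit=snr_unit,
                response_window=design.response_window,
            ))
    else:  # pragma: no cover
        raise ValueError(f"unknown session_type {st!r}")
    return trials


def filter_analyzable(trials: Sequence[Trial]) -> list[Trial]:
    """Drop stimulus-based/mixed1 trials lacking a pre-test sequence.

    Mirrors the task's analysis rule that such trials (38 per session) are
    discarded; all other trials pass through unchanged, order preserved.
    """
    return [
        t for t in trials
        if not (t.session_type in ("stim", "mixed1") and len(t.pretest) == 0)
    ]


# ---------------------------------------------------------------------------
# trial-table serialization

_COLUMNS = [
    "subject_id", "session_type", "block", "trial_index", "cue", "pretest",
    "tone", "snr_db", "snr_unit", "choice", "rt_s", "correct",
    "response_window_s",
]


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = [{
        "subject_id": t.subject_id, "session_type": t.session_type,
        "block": t.block, "trial_index": t.trial_index,
        "cue": t.cue.label if t.cue else "",
        "pretest": "".join(t.pretest),
        "tone": t.tone, "snr_db": t.snr_db, "snr_unit": t.snr_unit,
        "choice": t.choice, "rt_s": t.rt, "correct": t.correct,
        "response_window_s": t.response_window,
    } for t in trials]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    out = []
    for row in df.itertuples(index=False):
        cue = CUES[row.cue] if isinstance(row.cue, str) and row.cue else None
        pre = row.pretest if isinstance(row.pretest, str) else ""
        out.append(Trial(
            subject_id=str(row.subject_id), session_type=row.session_type,
            trial_index=int(row.trial_index), block=int(row.block), cue=cue,
            pretest=tuple(pre), tone=row.tone, snr_db=float(row.snr_db),
            snr_unit=float(row.snr_unit), choice=row.choice,
            rt=float(row.rt_s), correct=bool(row.correct),
            response_window=float(row.response_window_s),
        ))
    return out


def write_trials(trials: Sequence[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.8g")


def read_trials(path) -> list[Trial]:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"cue": str, "pretest": str, "choice": str})
    df["rt_s"] = pd.to_numeric(df["rt_s"], errors="coerce")
    return frame_to_trials(df)
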