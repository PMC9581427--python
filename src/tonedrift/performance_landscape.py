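"""DDM-predicted accuracy surfaces over (starting-point, evidence) bias pairs.

For a given expectation context (a low/high prior cue, or an LL/HH pre-test
ending), the predicted proportion of correct choices pc(z, v | c, theta) is
computed on a grid of candidate bias pairs, holding the subject's remaining
parameters fixed, averaging over the trial types (tone identity x |SNR|)
expected in that context.  Surfaces are normalized to proportion-of-maximum
and summarized by their 97%-of-maximum contour, the region of near-optimal
bias combinations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .ddm import DDMParams, TrialDrivers, solve_fpt, logistic
from .task_design import CUES, SNR_DB_LEVELS, map_snr

__all__ = ["PerformanceGrid", "performance_grid", "contour_97",
           "proportion_max"]

RULE_CONTEXTS = ("low", "high", "neutral")
STIM_CONTEXTS = ("LL", "HH")


@dataclass
class PerformanceGrid:
    z_grid: np.ndarray          # starting-point bias values (see notes below)
    v_grid: np.ndarray          # evidence-accumulation bias values
    accuracy: np.ndarray        # pc, shape (len(z_grid), len(v_grid))
    context: str
    subject_params: DDMParams
    boundary_flag: bool = False

    @property
    def norm_accuracy(self) -> np.ndarray:
        return self.accuracy / self.accuracy.max()

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.accuracy), self.accuracy.shape)
        return float(self.z_grid[i]), float(self.v_grid[j])


def _context_trial_mix(context: str) -> tuple[float, tuple | None]:
    """(p_high, pretest) for a context; pretest None for rule contexts."""
    if context in RULE_CONTEXTS:
        return CUES[context].p_high, None
    if context in STIM_CONTEXTS:
        # pre-test sequences are non-predictive of the test tone
        return 0.5, tuple(context)  # e.g. ("L", "L")
    raise ValueError(f"unknown context {context!r}")


def _p_correct(params: DDMParams, context: str, z: float, v: float,
               snr_levels, window: float, dt: float, dx: float) -> float:
    """Trial-type-weighted P(correct) for one candidate (z, v) bias pair.

    Rule contexts: z is the starting fraction the grid value denotes (the
    logit-scale cue bias is set to logit(z)); v replaces the cue's evidence
    bias.  Stimulus contexts: z and v replace z_Bias and v_Bias, with the
    adaptation weights held at their fitted values.
    """
    p_high, pretest = _context_trial_mix(context)
    if pretest is None:
        z_logit = math.log(z / (1.0 - z))
        bias_ev = v
        pt_bias = adapt = 0.0
    else:
        from .ddm import compute_pt_bias, compute_adapt
        pt_bias = compute_pt_bias(pretest, params.tau_bias)
        adapt = compute_adapt(pretest, params.va_high, params.va_low,
                              params.tau_va)
        z_logit = params.z_0 + z * pt_bias
        bias_ev = params.v_0 + v * pt_bias
    start = min(max(logistic(z_logit), 0.01), 0.99)
    ndt = params.ndt_0 + (params.ndt_bias * abs(pt_bias) if pretest else 0.0)
    ndt = max(ndt, 0.0)

    acc = 0.0
    w_snr = 1.0 / len(snr_levels)
    for tone, p_tone in (("H", p_high), ("L", 1.0 - p_high)):
        for snr_db in snr_levels:
            snr = map_snr(snr_db, tone)
            drift = params.v_snr * snr + bias_ev + adapt * abs(snr)
            drv = TrialDrivers(drift=drift, start_frac=start,
                               bound_half=params.B, collapse=params.t_B,
                               ndt=ndt, window=window)
            sol = solve_fpt(drv, dt=dt, dx=dx, horizon=max(window - ndt, dt))
            p_ddm = sol.p_upper() if tone == "H" else sol.p_lower()
            # lapse responds uniformly (correct half the time); window
            # expiry counts as incorrect
            acc += p_tone * w_snr * ((1 - params.lapse) * p_ddm
                                     + 0.5 * params.lapse)
    return acc


def performance_grid(params: DDMParams, context: str,
                     z_grid=None, v_grid=None,
                     snr_levels=SNR_DB_LEVELS, window: float = 2.0,
                     dt: float = 0.01, dx: float = 0.01) -> PerformanceGrid:
    """Predicted-accuracy surface over candidate (z, v) bias pairs."""
    if z_grid is None:
        z_grid = (np.linspace(0.1, 0.9, 17) if context in RULE_CONTEXTS
                  else np.linspace(-0.9, 0.9, 17))
    if v_grid is None:
        v_grid = np.linspace(-4.0, 4.0, 17)
    z_grid = np.asarray(z_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    if np.any(np.diff(z_grid) <= 0) or np.any(np.diff(v_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    if context in RULE_CONTEXTS and (z_grid.min() < 0.1 - 1e-9
                                     or z_grid.max() > 0.9 + 1e-9):
        warnings.warn("rule-context z grid outside the customary (.1, .9) range")
    if v_grid.min() < -4 - 1e-9 or v_grid.max() > 4 + 1e-9:
        warnings.warn("v grid outside the customary [-4, 4] range")

    acc = np.empty((z_grid.size, v_grid.size))
    for i, z in enumerate(z_grid):
        for j, v in enumerate(v_grid):
            acc[i, j] = _p_correct(params, context, z, v, snr_levels,
                                   window, dt, dx)
    return PerformanceGrid(z_grid=z_grid, v_grid=v_grid, accuracy=acc,
                           context=context, subject_params=params)


def contour_97(grid: PerformanceGrid, level: float = 0.97
               ) -> list[np.ndarray]:
    """Level-set polylines of the normalized surface at ``level``.

    Marching squares with bilinear interpolation; vertices are (z, v) pairs.
    If the whole grid sits at or above the level the grid boundary is
    returned and ``grid.boundary_flag`` set.
    """
    na = grid.norm_accuracy
    if na.min() >= level:
        grid.boundary_flag = True
        z0, z1 = grid.z_grid[0], grid.z_grid[-1]
        v0, v1 = grid.v_grid[0], grid.v_grid[-1]
        return [np.array([[z0, v0], [z0, v1], [z1, v1], [z1, v0], [z0, v0]])]
    contours = measure.find_contours(na, level)
    out = []
    for c in contours:
        z = np.interp(c[:, 0], np.arange(grid.z_grid.size), grid.z_grid)
        v = np.interp(c[:, 1], np.arange(grid.v_grid.size), grid.v_grid)
        out.append(np.column_stack([z, v]))
    return out


def proportion_max(grid: PerformanceGrid, z: float, v: float
                   ) -> tuple[float, bool]:
    """Normalized predicted accuracy at a subject's fitted (z, v) biases.

    Bilinear interpolation on the normalized surface; points outside the grid
    hull snap to the nearest cell and are flagged.
    """
    clipped = not (grid.z_grid[0] <= z <= grid.z_grid[-1]
                   and grid.v_grid[0] <= v <= grid.v_grid[-1])
    zq = float(np.clip(z, grid.z_grid[0], grid.z_grid[-1]))
    vq = float(np.clip(v, grid.v_grid[0], grid.v_grid[-1]))
    interp = RegularGridInterpolator((grid.z_grid, grid.v_grid),
                                     grid.norm_accuracy)
    return float(interp((zq, vq))), clipped
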