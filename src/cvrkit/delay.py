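"""Hemodynamic delay estimation by shift-and-search lagged regression.

The CO2 bolus reaches different brain regions at different times, and the
recording chain (gas sampling line) adds a global lag between the etCO2
trace and the BOLD series.  Both are handled by systematically time-shifting
the etCO2 regressor: the global delay is the shift maximizing correlation
with the whole-brain mean signal, and voxelwise delays are found by fitting
Y = b0 + b1 * etCO2(t - s) over a grid of shifts s and keeping the best fit.
Delays are reported relative to the global delay, so the global signal maps
to zero.

Sign convention: a positive shift moves the etCO2 regressor later in time,
so a positive (referenced) delay means the voxel responds later than the
global signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .physio import EtCO2Series
from .volume import BoldVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftGrid:
    """Symmetric grid of candidate time shifts.

    Parameters
    ----------
    max_shift : float
        Half-range in seconds; the grid spans [-max_shift, +max_shift].
        The default (30 s) covers typical sampling-line delays (~10 s) plus
        physiological arrival-time spreads.
    step : float
        Grid step in seconds (default 0.5 s, sub-TR resolution).
    """

    max_shift: float = 30.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValidationError(f"shift step must be positive, got {self.step}")
        if self.max_shift < 0:
            raise ValidationError(f"shift range must be non-negative, got {self.max_shift}")

    @property
    def shifts(self) -> np.ndarray:
        """Strictly increasing shifts, always containing 0."""
        n = int(round(self.max_shift / self.step))
        return np.arange(-n, n + 1) * self.step


@dataclass
class LagFitResult:
    """Voxelwise lagged-GLM fit at the optimal shift.

    All maps are NaN outside the brain mask.  ``delay_map`` is referenced to
    the global delay (global signal -> 0 s).  ``beta1_map`` is in BOLD units
    per mmHg; ``rmax_map`` is the signed Pearson r at the optimum.
    """

    delay_map: np.ndarray
    beta0_map: np.ndarray
    beta1_map: np.ndarray
    rmax_map: np.ndarray
    global_delay: float
    n_degenerate: int = 0


def build_shifted_regressor(
    etco2: EtCO2Series, shift: float, frame_times: np.ndarray
) -> np.ndarray:
    """Sample etCO2(t - shift) on the BOLD frame grid.

    Frames whose shifted time falls outside the recording support get the
    baseline value — a robust baseline extrapolation that never requires
    trimming the BOLD series.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    return etco2.sample(frame_times - shift)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(xc @ yc / (nx * ny))


def find_global_delay(
    global_signal: np.ndarray,
    etco2: EtCO2Series,
    grid: ShiftGrid,
    frame_times: np.ndarray,
) -> float:
    """Shift maximizing the correlation between etCO2 and the mean BOLD signal.

    Ties are broken toward the smallest absolute shift.  Raises on a
    constant global signal, which cannot be aligned.
    """
    global_signal = np.asarray(global_signal, dtype=float)
    if np.ptp(global_signal) == 0:
        raise ValidationError("degenerate global signal (zero temporal variance)")
    best_r = -np.inf
    best_shift = 0.0
    # visiting shifts by increasing |s| makes 'strictly greater' a tie-break
    for s in sorted(grid.shifts, key=lambda v: (abs(v), v)):
        r = _pearson(build_shifted_regressor(etco2, s, frame_times), global_signal)
        if r > best_r:
            best_r = r
            best_shift = float(s)
    return best_shift


def voxelwise_lag_glm(
    bold: BoldVolume,
    etco2: EtCO2Series,
    grid: ShiftGrid,
    global_delay: float,
) -> LagFitResult:
    """Fit Y = b0 + b1 * etCO2(t - s) per voxel over shifts centred on the global delay.

    For a single regressor plus intercept, maximizing |r| and minimizing the
    residual sum of squares select the same shift; |r| is used so that
    negative (pathological) responses are found too, with the sign of b1
    preserved.  Ties go to the shift closest to the global delay (smallest
    referenced delay), then to the smaller shift.

    Voxels with zero temporal variance get delay 0, b1 = 0 and are counted
    in ``n_degenerate``.
    """
    frame_times = bold.frame_times
    if etco2.sample(frame_times).shape[0] != bold.n_frames:
        raise ValidationError("frame grid inconsistent with BOLD series")

    mask = bold.mask
    Y = bold.data[mask].T  # (T, V)
    T, V = Y.shape
    Ym = Y.mean(axis=0)
    Yc = Y - Ym
    Ynorm = np.linalg.norm(Yc, axis=0)
    degenerate = Ynorm == 0
    safe_ynorm = np.where(degenerate, 1.0, Ynorm)

    shifts = global_delay + grid.shifts
    # preference order for exact ties: |referenced delay| first, then smaller shift
    order = sorted(range(shifts.size), key=lambda i: (abs(grid.shifts[i]), shifts[i]))

    best_absr = np.full(V, -1.0)
    best_idx = np.zeros(V, dtype=int)
    r_signed = np.zeros((shifts.size, V))
    for i in order:
        x = build_shifted_regressor(etco2, shifts[i], frame_times)
        xc = x - x.mean()
        xnorm = np.linalg.norm(xc)
        if xnorm == 0:
            continue  # fully padded regressor carries no information
        r = (xc @ Yc) / (xnorm * safe_ynorm)
        r_signed[i] = r
        absr = np.abs(r)
        better = absr > best_absr
        best_absr[better] = absr[better]
        best_idx[better] = i

    beta0 = np.empty(V)
    beta1 = np.empty(V)
    rmax = np.empty(V)
    for i in np.unique(best_idx):
        sel = best_idx == i
        x = build_shifted_regressor(etco2, shifts[i], frame_times)
        xc = x - x.mean()
        ss = xc @ xc
        b1 = (xc @ Yc[:, sel]) / ss if ss > 0 else np.zeros(sel.sum())
        beta1[sel] = b1
        beta0[sel] = Ym[sel] - b1 * x.mean()
        rmax[sel] = r_signed[i, sel]

    delays = shifts[best_idx] - global_delay
    delays[degenerate] = 0.0
    beta1[degenerate] = 0.0
    beta0[degenerate] = Ym[degenerate]
    rmax[degenerate] = 0.0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("%d in-mask voxels have zero temporal variance; delay set to 0", n_degenerate)

    def _to_map(values: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = values
        return out

    return LagFitResult(
        delay_map=_to_map(delays),
        beta0_map=_to_map(beta0),
        beta1_map=_to_map(beta1),
        rmax_map=_to_map(rmax),
        global_delay=float(global_delay),
        n_degenerate=n_degenerate,
    )
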