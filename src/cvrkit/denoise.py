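"""CO2-aware refinement of ICA noise labels and non-aggressive denoising.

Upstream motion-artefact classifiers (ICA-AROMA style) were designed for
paradigms where physiological fluctuations are a nuisance.  In CVR mapping
the CO2-driven fluctuation *is* the signal, so any "noise" component that
correlates with the etCO2 timecourse must be rescued before denoising.
Components are compared with the etCO2 regressor at its best shift over the
delay-search grid, since the global delay is unknown at this stage, and the
absolute correlation is thresholded (default 0.6, a moderate correlation)
so anti-correlated CO2 components are rescued too.

Denoising is non-aggressive: the full mixing matrix (plus intercept) is fit
to each voxel by ordinary least squares and only the fitted contribution of
the remaining noise components is subtracted, preserving variance shared
with signal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

from .delay import ShiftGrid, build_shifted_regressor
from .errors import ValidationError
from .physio import EtCO2Series
from .volume import BoldVolume

logger = logging.getLogger(__name__)

#: Default |r| threshold above which a noise IC is reclassified as signal.
DEFAULT_IC_THRESHOLD = 0.6


@dataclass
class ICDecomposition:
    """IC mixing matrix (component timecourses) with upstream noise labels.

    ``mixing`` is T x K (one column per component); ``noise_indices`` are
    0-based indices of components labelled noise upstream.
    """

    mixing: np.ndarray
    noise_indices: frozenset[int]

    def __post_init__(self) -> None:
        self.mixing = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        self.noise_indices = frozenset(int(i) for i in self.noise_indices)
        k = self.k
        bad = [i for i in self.noise_indices if not 0 <= i < k]
        if bad:
            raise ValidationError(f"noise IC indices {sorted(bad)} out of range for K={k}")
        if np.any(np.all(self.mixing == 0, axis=0)):
            raise ValidationError("mixing matrix contains an all-zero component column")

    @property
    def n_frames(self) -> int:
        return self.mixing.shape[0]

    @property
    def k(self) -> int:
        return self.mixing.shape[1]


@dataclass
class ReclassificationRecord:
    """Outcome of the CO2-aware noise-label refinement, persisted for the report."""

    correlations: np.ndarray  # signed r at the maximizing shift, per IC
    best_shifts: np.ndarray  # maximizing shift in seconds, per IC
    threshold: float
    original_noise_indices: frozenset[int]
    rescued_indices: frozenset[int] = field(init=False)
    final_noise_indices: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        rescued = {
            i
            for i in self.original_noise_indices
            if abs(self.correlations[i]) >= self.threshold
        }
        self.rescued_indices = frozenset(rescued)
        self.final_noise_indices = frozenset(self.original_noise_indices - rescued)


def correlate_ics_with_etco2(
    decomp: ICDecomposition,
    etco2: EtCO2Series,
    frame_times: np.ndarray,
    grid: ShiftGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-shift correlation of each IC timecourse with the etCO2 regressor.

    For every component the Pearson r against etCO2(t - s) is maximized in
    absolute value over the shift grid; the signed r and the maximizing
    shift are returned (arrays of length K).  A zero-variance component gets
    r = 0 with a logged warning.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if decomp.n_frames != frame_times.size:
        raise ValidationError(
            f"mixing matrix has {decomp.n_frames} rows but {frame_times.size} frames expected"
        )
    M = decomp.mixing
    Mc = M - M.mean(axis=0)
    mnorm = np.linalg.norm(Mc, axis=0)
    flat = mnorm == 0
    if flat.any():
        logger.warning(
            "components %s have zero variance; correlation set to 0",
            sorted(np.flatnonzero(flat).tolist()),
        )
    safe_mnorm = np.where(flat, 1.0, mnorm)

    best_r = np.zeros(decomp.k)
    best_shift = np.zeros(decomp.k)
    best_absr = np.full(decomp.k, -1.0)
    for s in sorted(grid.shifts, key=lambda v: (abs(v), v)):
        x = build_shifted_regressor(etco2, s, frame_times)
        xc = x - x.mean()
        xnorm = np.linalg.norm(xc)
        if xnorm == 0:
            continue
        r = (xc @ Mc) / (xnorm * safe_mnorm)
        r[flat] = 0.0
        better = np.abs(r) > best_absr
        best_absr[better] = np.abs(r)[better]
        best_r[better] = r[better]
        best_shift[better] = s
    return best_r, best_shift


def reclassify_noise(
    decomp: ICDecomposition,
    correlations: np.ndarray,
    best_shifts: np.ndarray | None = None,
    threshold: float = DEFAULT_IC_THRESHOLD,
) -> ReclassificationRecord:
    """Rescue noise ICs whose |r| with etCO2 reaches the threshold."""
    if not 0 <= threshold <= 1:
        raise ValidationError(f"IC threshold must be in [0, 1], got {threshold}")
    correlations = np.asarray(correlations, dtype=float)
    if best_shifts is None:
        best_shifts = np.zeros_like(correlations)
    record = ReclassificationRecord(
        correlations=correlations,
        best_shifts=np.asarray(best_shifts, dtype=float),
        threshold=float(threshold),
        original_noise_indices=decomp.noise_indices,
    )
    if record.rescued_indices:
        logger.info(
            "rescued %d CO2-related component(s) from the noise set: %s",
            len(record.rescued_indices),
            sorted(record.rescued_indices),
        )
    return record


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        collinear = sorted(int(p) - 1 for p in piv[rank:] if p > 0)  # drop intercept col 0
        raise ValidationError(
            f"mixing matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear component columns: {collinear}"
        )


def nonaggressive_denoise(
    bold: BoldVolume,
    decomp: ICDecomposition,
    final_noise_indices: frozenset[int] | set[int],
) -> BoldVolume:
    """Subtract the OLS-fitted contribution of noise components per voxel.

    The full mixing matrix plus an intercept is regressed onto every in-mask
    timecourse and only the noise columns' fitted contribution is removed;
    voxels outside the mask are untouched.  With an empty noise set the
    output equals the input.
    """
    if decomp.n_frames != bold.n_frames:
        raise ValidationError(
            f"mixing matrix rows ({decomp.n_frames}) != BOLD frames ({bold.n_frames})"
        )
    noise = sorted(int(i) for i in final_noise_indices)
    bad = [i for i in noise if not 0 <= i < decomp.k]
    if bad:
        raise ValidationError(f"noise IC indices {bad} out of range for K={decomp.k}")

    data = bold.data.copy()
    if noise:
        X = np.column_stack([np.ones(bold.n_frames), decomp.mixing])
        _check_full_rank(X)
        Y = bold.data[bold.mask].T  # (T, V)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        noise_cols = [i + 1 for i in noise]  # +1 skips the intercept
        fitted_noise = X[:, noise_cols] @ coef[noise_cols]
        data[bold.mask] = (Y - fitted_noise).T
    return BoldVolume(data=data, affine=bold.affine, mask=bold.mask, tr=bold.tr)
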