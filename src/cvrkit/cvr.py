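"""Voxelwise cerebrovascular reactivity from lagged-GLM fits.

With the BOLD model Y = b0 + b1 * etCO2(t - s_opt), the fractional BOLD
change per mmHg of CO2 around the resting operating point is

    CVR = 100 * b1 / (b0 + b1 * etCO2_baseline)   [%BOLD / mmHg]

The denominator is the model's predicted BOLD level at baseline CO2; the
factor 100 expresses the result in percent signal change.  Voxels whose
baseline-predicted signal is non-positive (or numerically indistinguishable
from zero) have no meaningful percent change and are masked out as NaN
rather than clipped — missingness must stay visible to clinical users.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .delay import LagFitResult
from .errors import ValidationError
from .physio import EtCO2Series

logger = logging.getLogger(__name__)

#: Relative tolerance below which the denominator counts as degenerate.
DENOMINATOR_RTOL = 1e-6


@dataclass
class CvrResult:
    """Voxelwise CVR and delay maps with a validity mask.

    ``cvr_map`` is in %BOLD/mmHg, ``delay_map`` in seconds referenced so the
    global signal's delay is zero.  Both are NaN outside ``valid_mask`` /
    the brain mask respectively.
    """

    cvr_map: np.ndarray
    delay_map: np.ndarray
    valid_mask: np.ndarray
    global_delay: float


def compute_cvr(beta0, beta1, baseline: float):
    """Elementwise CVR = 100 * b1 / (b0 + b1 * baseline), NaN where degenerate.

    Works on scalars or arrays.  Degenerate voxels are those with
    denominator <= 0 or |denominator| < 1e-6 * |b1 * baseline|.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    denom = beta0 + beta1 * baseline
    with np.errstate(invalid="ignore", divide="ignore"):
        invalid = ~(denom > 0) | (np.abs(denom) < DENOMINATOR_RTOL * np.abs(beta1 * baseline))
        cvr = np.where(invalid, np.nan, 100.0 * beta1 / np.where(invalid, 1.0, denom))
    if cvr.ndim == 0:
        return float(cvr)
    return cvr


def assemble_result(
    lagfit: LagFitResult, etco2: EtCO2Series, mask: np.ndarray
) -> CvrResult:
    """Apply the CVR formula inside the mask and bundle the output maps."""
    mask = np.asarray(mask).astype(bool)
    if lagfit.beta0_map.shape != mask.shape:
        raise ValidationError(
            f"fitted maps {lagfit.beta0_map.shape} do not match mask {mask.shape}"
        )
    cvr = np.asarray(compute_cvr(lagfit.beta0_map, lagfit.beta1_map, etco2.baseline))
    cvr[~mask] = np.nan
    valid = mask & np.isfinite(cvr)
    n_masked = int(mask.sum() - valid.sum())
    if n_masked:
        logger.warning("%d in-mask voxels have degenerate CVR denominators (set NaN)", n_masked)
    delay = lagfit.delay_map.copy()
    delay[~mask] = np.nan
    return CvrResult(
        cvr_map=cvr,
        delay_map=delay,
        valid_mask=valid,
        global_delay=lagfit.global_delay,
    )
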