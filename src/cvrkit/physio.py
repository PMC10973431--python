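"""End-tidal CO2 (etCO2) extraction from raw capnograph recordings.

A capnograph samples CO2 concentration at the mouth continuously, so the
recording oscillates with every breath between near-zero (inspiration) and
the alveolar plateau (end of expiration).  The physiologically meaningful
quantity is the upper envelope of that oscillation — the end-tidal CO2 —
which tracks arterial CO2 partial pressure.  This module turns a raw trace
into a smoothed, unit-correct etCO2 timecourse with a baseline value, and
resamples it onto the BOLD frame grid with baseline padding where the
recording does not cover the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default dry barometric pressure used for %-to-mmHg conversion.
DEFAULT_BAROMETRIC_PRESSURE = 760.0

#: Minimum plausible breath period in seconds (40 breaths/min upper bound).
DEFAULT_MIN_BREATH_PERIOD = 1.5

_UNIT_ALIASES = {
    "percent": "percent",
    "%": "percent",
    "mmhg": "mmHg",
}


def _normalize_units(units: str) -> str:
    key = str(units).strip().lower()
    if key not in _UNIT_ALIASES:
        raise ValidationError(
            f"unsupported CO2 units {units!r} in physio sidecar field 'Units' "
            "(expected 'percent'/'%' or 'mmHg')"
        )
    return _UNIT_ALIASES[key]


@dataclass
class CapnoTrace:
    """Raw breath-CO2 sample series.

    Attributes
    ----------
    samples : ndarray
        CO2 concentration samples in ``units``.
    sampling_frequency : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds, on the BOLD clock (first BOLD
        volume at t=0); may be negative if the recording started earlier.
    units : str
        Either ``"percent"`` or ``"mmHg"``.
    """

    samples: np.ndarray
    sampling_frequency: float
    start_time: float = 0.0
    units: str = "mmHg"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.units = _normalize_units(self.units)
        if not self.sampling_frequency > 0:
            raise ValidationError(
                f"sampling frequency must be positive, got {self.sampling_frequency}"
            )
        if self.samples.ndim != 1:
            raise ValidationError("CO2 samples must be a 1D series")
        if not np.isfinite(self.samples).all():
            raise ValidationError("CO2 samples contain non-finite values")
        if self.duration < 2 * DEFAULT_MIN_BREATH_PERIOD:
            raise ValidationError(
                f"CO2 recording too short ({self.duration:.2f} s): need at least "
                "two breaths' worth of samples"
            )

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on the BOLD clock."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_frequency

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_frequency


@dataclass
class EtCO2Series:
    """Smoothed end-tidal CO2 timecourse in mmHg.

    ``baseline`` is the resting-state etCO2 level used both for baseline
    padding outside ``source_support`` and as the operating point of the CVR
    computation.
    """

    values: np.ndarray
    time_points: np.ndarray
    baseline: float
    source_support: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.values.shape != self.time_points.shape:
            raise ValidationError("etCO2 values and time points must align")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValidationError("etCO2 time points must be strictly increasing")
        lo, hi = float(self.values.min()), float(self.values.max())
        if not (lo <= self.baseline <= hi):
            raise ValidationError(
                f"baseline {self.baseline:.2f} mmHg outside envelope range [{lo:.2f}, {hi:.2f}]"
            )

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the envelope at arbitrary times, baseline outside support."""
        times = np.asarray(times, dtype=float)
        out = np.interp(times, self.time_points, self.values)
        t0, t1 = self.source_support
        out = np.where((times < t0) | (times > t1), self.baseline, out)
        return out


def convert_units(
    trace: CapnoTrace, barometric_pressure: float = DEFAULT_BAROMETRIC_PRESSURE
) -> CapnoTrace:
    """Convert a capnograph trace to mmHg.

    Percent CO2 is converted to partial pressure with a dry barometric
    pressure (default 760 mmHg, sea level, no water-vapour correction);
    traces already in mmHg pass through unchanged.
    """
    if trace.units == "mmHg":
        return trace
    return CapnoTrace(
        samples=trace.samples * (barometric_pressure / 100.0),
        sampling_frequency=trace.sampling_frequency,
        start_time=trace.start_time,
        units="mmHg",
    )


def detect_expiratory_peaks(
    trace: CapnoTrace, min_breath_period: float = DEFAULT_MIN_BREATH_PERIOD
) -> np.ndarray:
    """Locate end-of-expiration peaks (one per breath) in a mmHg trace.

    Local maxima separated by at least ``min_breath_period`` and with a
    prominence of at least 25% of the trace inter-quartile range, which
    rejects cardiogenic ripples riding on the expiratory plateau.
    """
    if trace.units != "mmHg":
        raise ValidationError("peak detection expects a trace in mmHg; convert units first")
    x = trace.samples
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    prominence = 0.25 * iqr if iqr > 0 else None
    distance = max(1, int(round(min_breath_period * trace.sampling_frequency)))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size < 2:
        raise ValidationError("no breathing pattern detected in CO2 recording")
    return peaks


def compute_etco2(
    trace: CapnoTrace,
    smoothing_window: float = 10.0,
    baseline_fraction: float = 0.10,
    min_breath_period: float = DEFAULT_MIN_BREATH_PERIOD,
) -> EtCO2Series:
    """Extract the smoothed upper envelope (etCO2) of a breathing trace.

    The envelope interpolates linearly through the expiratory peaks on the
    trace's native grid (edge-held at the boundaries), then a
    Savitzky-Golay filter (quadratic, ``smoothing_window`` seconds wide)
    removes breath-to-breath jitter.  A polynomial-preserving kernel is
    used rather than a plain moving average because the envelope *is* the
    stimulus regressor: a boxcar attenuates the slow block waveform by
    1-2%, which would propagate multiplicatively into every CVR value,
    while the Savitzky-Golay passband leaves it essentially untouched.
    The baseline is the mean of the lowest ``baseline_fraction`` quantile
    of envelope samples, robust to designs in which hypercapnia occupies
    most of the run.

    Parameters
    ----------
    trace : CapnoTrace
        Recording in mmHg.
    smoothing_window : float
        Moving-average width in seconds (default 10 s, a light smoothing).
    baseline_fraction : float
        Quantile of lowest envelope values averaged into the baseline.
    """
    peaks = detect_expiratory_peaks(trace, min_breath_period=min_breath_period)
    t = trace.times
    envelope = np.interp(t, t[peaks], trace.samples[peaks])
    window = int(round(smoothing_window * trace.sampling_frequency))
    window += 1 - window % 2  # Savitzky-Golay needs an odd length
    if window > 3 and window <= envelope.size:
        envelope = savgol_filter(envelope, window_length=window, polyorder=2,
                                 mode="nearest")
    threshold = np.quantile(envelope, baseline_fraction)
    baseline = float(envelope[envelope <= threshold].mean())
    return EtCO2Series(
        values=envelope,
        time_points=t,
        baseline=baseline,
        source_support=(float(t[0]), float(t[-1])),
    )


def pad_and_sample(etco2: EtCO2Series, frame_times: np.ndarray) -> np.ndarray:
    """Sample the etCO2 envelope on the BOLD frame grid with baseline padding.

    Frames falling outside the recording's support receive the baseline
    value, so a recording shorter than the scan never forces trimming of
    the BOLD series.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.ndim != 1 or np.any(np.diff(frame_times) <= 0):
        raise ValidationError("frame times must be a strictly increasing 1D array")
    return etco2.sample(frame_times)
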