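"""Signal conditioning ahead of spectral analysis and envelope metrics.

The coherence estimator assumes stationary, zero-mean, unit-variance series.
Raw surface EMG is therefore (optionally) band-pass filtered, full-wave
rectified, and normalised to unit variance, in that fixed order; the applied
steps are recorded in the output's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateSignalError, ValidationError


@dataclass
class ConditionedSignal:
    """A conditioned (zero-mean, unit-variance) signal ready for spectral analysis."""

    values: np.ndarray
    fs: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")


def bandpass(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output has the same length as input.

    The upper edge is capped at 0.45*fs so the analogue recording band
    (e.g. 5 Hz - 1 kHz at fs = 2 kHz) remains applicable digitally.
    """
    x = np.asarray(x, dtype=float).ravel()
    hi_hz = min(hi_hz, 0.45 * fs)
    if not 0 < lo_hz < hi_hz:
        raise ValidationError(f"invalid band ({lo_hz}, {hi_hz}) at fs={fs}")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def normalize_unit_variance(x: np.ndarray, fs: float, provenance: list[str] | None = None) -> ConditionedSignal:
    """Centre and scale to exactly zero mean and unit variance (1/N convention)."""
    x = np.asarray(x, dtype=float).ravel()
    sd = float(np.std(x))  # population (1/N) convention
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise DegenerateSignalError("constant signal cannot be normalised to unit variance")
    values = (x - np.mean(x)) / sd
    steps = list(provenance or []) + ["normalize"]
    return ConditionedSignal(values=values, fs=fs, provenance=steps)


def condition_emg(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
) -> ConditionedSignal:
    """Apply the fixed conditioning pipeline: [bandpass ->] rectify -> normalize.

    ``band=None`` skips filtering (appropriate for synthetic signals that carry
    no out-of-band content).  The order is not configurable; the steps applied
    are recorded in the returned provenance.
    """
    steps: list[str] = []
    y = np.asarray(x, dtype=float).ravel()
    if band is not None:
        y = bandpass(y, band[0], band[1], fs)
        steps.append(f"bandpass({band[0]},{band[1]})")
    y = rectify(y)
    steps.append("rectify")
    return normalize_unit_variance(y, fs, provenance=steps)


def smooth_envelope(x: np.ndarray, window_ms: float, fs: float) -> np.ndarray:
    """Centred moving average of a rectified signal; edges use a shrinking window."""
    x = np.asarray(x, dtype=float).ravel()
    if window_ms <= 0:
        raise ValidationError("window_ms must be positive")
    w = max(1, int(round(window_ms / 1000.0 * fs)))
    if w > x.size:
        raise ValidationError(f"window of {w} samples longer than signal ({x.size})")
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
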