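"""Two-channel spectral analysis by disjoint-segment periodogram averaging.

The record is split into L disjoint, non-overlapping, untapered segments of
T = fs / resolution samples (trailing partial segment discarded); each segment
is demeaned and its periodogram and cross-periodogram accumulated:

    f_xx(k) = <|X_k|^2> / T^2,   f_xy(k) = <conj(X_k) Y_k> / T^2

so that sum_k f_xx equals the segment-mean signal power (Parseval).  Coherence
is |f_xy|^2 / (f_xx f_yy), bounded in [0, 1] by Cauchy-Schwarz over segments,
with the exact upper 95% confidence limit 1 - alpha^(1/(L-1)) for this
estimator class under independence.  The cumulant density

    q_xy(u) = T * IDFT[f_xy](u)  =  (1/T) sum_n x_n y_{n+u}

is the time-domain counterpart (a cross-correlogram on the +/-250 ms lag
range), with flat +/-1.96*sqrt(sum_k f_xx f_yy / L) confidence limits under
the independence null.  With this sign convention a positive lag means the
second channel follows the first, and the phase of (x, x delayed by d) is
-2*pi*lambda*d.

Cross-talk between electrodes mimics common drive; it is screened by its
signature — high coherence across a broad frequency range combined with a
significant cumulant peak at (near) zero lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, ValidationError
from .preprocess import ConditionedSignal

QC_FREQ_RANGE = (1.0, 60.0)  # Hz; band statistics and QC are read in this range


@dataclass
class SpectralEstimate:
    """Auto-/cross-spectra, coherence and phase for one channel pair.

    One-sided arrays run from 0 to the Nyquist frequency; the full-axis
    cross-spectrum needed for the cumulant density is retained internally.
    """

    freqs: np.ndarray          # Hz, 0..Nyquist
    f_xx: np.ndarray
    f_yy: np.ndarray
    f_xy: np.ndarray           # complex
    coherence: np.ndarray      # R^2 in [0, 1]
    phase: np.ndarray          # radians in [-pi, pi]
    L: int                     # number of disjoint segments
    T: int                     # segment length in samples
    fs: float
    coh_cl: float              # upper 95% confidence limit for R^2
    alpha: float = 0.05
    f_xx_full: np.ndarray | None = None
    f_yy_full: np.ndarray | None = None
    f_xy_full: np.ndarray | None = None

    def band_slice(self, lo_hz: float, hi_hz: float, closed: str = "both") -> np.ndarray:
        """Boolean mask over ``freqs`` for a band; ``closed`` in {left, both}."""
        if closed == "left":
            return (self.freqs >= lo_hz) & (self.freqs < hi_hz)
        if closed == "both":
            return (self.freqs >= lo_hz) & (self.freqs <= hi_hz)
        raise ValidationError(f"closed must be 'left' or 'both', got {closed!r}")


@dataclass
class CumulantDensity:
    """Time-domain correlation structure with flat 95% limits under independence."""

    lags: np.ndarray        # seconds, symmetric about 0
    q: np.ndarray
    cl_upper: float
    cl_lower: float

    @property
    def peak_index(self) -> int:
        """Index of the largest |q|; exact ties resolved to the smallest |lag|."""
        a = np.abs(self.q)
        best = np.flatnonzero(a == a.max())
        return int(best[np.argmin(np.abs(self.lags[best]))])

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags[self.peak_index])


@dataclass
class CrosstalkReport:
    """Outcome of the cross-talk screen for one record pair."""

    broadband_fraction: float
    zero_lag_peak: bool
    peak_lag_ms: float
    flagged: bool


def coherence_confidence_limit(L: int, alpha: float = 0.05) -> float:
    """Exact upper (1-alpha) limit for estimated coherence under independence."""
    if L < 2:
        raise InsufficientDataError("confidence limit requires at least 2 segments")
    return 1.0 - alpha ** (1.0 / (L - 1))


def _as_values(x) -> tuple[np.ndarray, float | None]:
    if isinstance(x, ConditionedSignal):
        return x.values, x.fs
    return np.asarray(x, dtype=float).ravel(), None


def estimate_spectra(
    x: ConditionedSignal | np.ndarray,
    y: ConditionedSignal | np.ndarray,
    resolution_hz: float = 1.0,
    fs: float | None = None,
    alpha: float = 0.05,
) -> SpectralEstimate:
    """Estimate auto-/cross-spectra, coherence and phase for a signal pair.

    Parameters
    ----------
    x, y : ConditionedSignal or array
        Equal-length series sharing one sampling rate (pass ``fs`` for bare
        arrays).
    resolution_hz : float
        Frequency resolution; the segment length is T = fs / resolution_hz.
    """
    xv, fx = _as_values(x)
    yv, fy = _as_values(y)
    if fx is not None and fy is not None and fx != fy:
        raise ValidationError(f"sampling rates differ: {fx} vs {fy}")
    fs = fs if fs is not None else (fx if fx is not None else fy)
    if fs is None:
        raise ValidationError("sampling rate unknown; pass fs or ConditionedSignal")
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")

    T_float = fs / resolution_hz
    if abs(T_float - round(T_float)) > 1e-9:
        raise ValidationError(
            f"resolution {resolution_hz} Hz does not divide fs={fs} evenly"
        )
    T = int(round(T_float))
    L = xv.size // T
    if L < 2:
        raise InsufficientDataError(
            f"need at least 2 segments of {T} samples, have {xv.size}"
        )

    xs = xv[: L * T].reshape(L, T)
    ys = yv[: L * T].reshape(L, T)
    xs = xs - xs.mean(axis=1, keepdims=True)  # per-segment demeaning
    ys = ys - ys.mean(axis=1, keepdims=True)

    X = np.fft.fft(xs, axis=1)
    Y = np.fft.fft(ys, axis=1)
    f_xx_full = np.mean(np.abs(X) ** 2, axis=0) / T**2
    f_yy_full = np.mean(np.abs(Y) ** 2, axis=0) / T**2
    f_xy_full = np.mean(np.conj(X) * Y, axis=0) / T**2

    n_half = T // 2 + 1
    freqs = np.arange(n_half) * (fs / T)
    f_xx = f_xx_full[:n_half]
    f_yy = f_yy_full[:n_half]
    f_xy = f_xy_full[:n_half]

    denom = f_xx * f_yy
    # segment demeaning voids the DC bin; treat near-zero denominators as empty
    active = denom > 1e-14 * float(denom.max() if denom.size else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(active, np.abs(f_xy) ** 2 / np.where(active, denom, 1.0), 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.where(active, np.angle(f_xy), 0.0)

    return SpectralEstimate(
        freqs=freqs, f_xx=f_xx, f_yy=f_yy, f_xy=f_xy,
        coherence=coh, phase=phase, L=L, T=T, fs=fs,
        coh_cl=coherence_confidence_limit(L, alpha), alpha=alpha,
        f_xx_full=f_xx_full, f_yy_full=f_yy_full, f_xy_full=f_xy_full,
    )


def _cumulant_from_full_xspec(
    f_xy_full: np.ndarray,
    var_q: float,
    T: int,
    fs: float,
    max_lag_s: float,
    scale: float,
) -> CumulantDensity:
    q_all = np.real(np.fft.ifft(f_xy_full)) * scale
    lags_all = np.arange(T)
    lags_all[lags_all > T // 2] -= T  # wrap to signed lags
    max_lag = min(int(round(max_lag_s * fs)), T // 2 - 1)
    order = np.argsort(lags_all, kind="stable")
    lags_sorted = lags_all[order]
    q_sorted = q_all[order]
    keep = np.abs(lags_sorted) <= max_lag
    cl = 1.96 * np.sqrt(var_q)
    return CumulantDensity(
        lags=lags_sorted[keep] / fs, q=q_sorted[keep], cl_upper=cl, cl_lower=-cl
    )


def cumulant_density(est: SpectralEstimate, max_lag_s: float = 0.25) -> CumulantDensity:
    """Cumulant density q_xy(u) of one estimate, restricted to |u| <= max_lag_s.

    The independence-null variance is lag-constant, sum_k f_xx(k) f_yy(k) / L
    over the full frequency axis, giving flat +/-1.96*sqrt(var) limits.
    """
    if est.f_xy_full is None:
        raise ValidationError("estimate lacks full-axis spectra")
    var_q = float(np.sum(est.f_xx_full * est.f_yy_full) / est.L)
    return _cumulant_from_full_xspec(
        est.f_xy_full, var_q, est.T, est.fs, max_lag_s, scale=float(est.T)
    )


def crosstalk_qc(
    est: SpectralEstimate,
    cum: CumulantDensity,
    broadband_threshold: float = 0.1,
    zero_lag_ms: float = 3.0,
) -> CrosstalkReport:
    """Screen a record pair for electrode cross-talk.

    Flags when coherence exceeds its 95% limit over more than
    ``broadband_threshold`` of the 1-60 Hz bins AND the dominant cumulant peak
    is significant and lies within ``zero_lag_ms`` of zero lag — the joint
    signature of instantaneous signal mixing, as opposed to genuine common
    drive, which is band-limited and lagged by conduction-delay differences.
    """
    mask = est.band_slice(*QC_FREQ_RANGE, closed="both")
    broadband_fraction = float(np.mean(est.coherence[mask] > est.coh_cl))
    peak_lag_ms = cum.peak_lag_s * 1000.0
    significant_peak = abs(cum.q[cum.peak_index]) > cum.cl_upper
    zero_lag_peak = bool(significant_peak and abs(peak_lag_ms) <= zero_lag_ms)
    return CrosstalkReport(
        broadband_fraction=broadband_fraction,
        zero_lag_peak=zero_lag_peak,
        peak_lag_ms=float(peak_lag_ms),
        flagged=bool(broadband_fraction > broadband_threshold and zero_lag_peak),
    )
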