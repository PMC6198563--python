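"""Band-restricted coherence areas, log transform, and group statistics.

Coherence in the alpha (5-15 Hz) and beta (15-35 Hz) bands is summarised as
the sum of per-bin coherence over the band ("area").  The two bands share the
15 Hz endpoint; to avoid double counting, the alpha band is taken half-open
[5, 15) and the beta band closed [15, 35].  Areas are log10-transformed to
symmetrise their distribution before group comparison by Student's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import AnalysisConfig
from .spectral import SpectralEstimate


@dataclass
class BandArea:
    """Summed coherence over one frequency band, with its log10."""

    band: tuple[float, float]
    area: float
    log_area: float  # nan when area == 0

    @property
    def log_defined(self) -> bool:
        return np.isfinite(self.log_area)


@dataclass
class BandComparison:
    """Two-sample Student's t comparison of log10 band areas."""

    t: float
    p: float
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    n_excluded: int  # undefined (zero-area) logs dropped


def band_area(
    est: SpectralEstimate, band: tuple[float, float], closed: str = "left"
) -> BandArea:
    """Sum coherence over integer-resolution bins in ``band``.

    ``closed="left"`` uses [lo, hi) (alpha convention); ``closed="both"`` uses
    [lo, hi] (beta convention, so the shared 15 Hz bin is counted once).
    """
    lo, hi = band
    if not lo < hi:
        raise ValidationError(f"empty band {band}")
    if hi > est.freqs[-1]:
        raise ValidationError(f"band {band} outside estimated range (max {est.freqs[-1]} Hz)")
    mask = est.band_slice(lo, hi, closed=closed)
    area = float(np.sum(est.coherence[mask]))
    with np.errstate(divide="ignore"):
        log_area = float(np.log10(area)) if area > 0 else float("nan")
    return BandArea(band=(lo, hi), area=area, log_area=log_area)


def alpha_beta_areas(
    est: SpectralEstimate, config: AnalysisConfig | None = None
) -> dict[str, BandArea]:
    """Alpha and beta band areas with the shared-endpoint convention applied."""
    config = config or AnalysisConfig()
    return {
        "alpha": band_area(est, config.alpha_band, closed="left"),
        "beta": band_area(est, config.beta_band, closed="both"),
    }


def compare_band_areas(
    group_a: Sequence[BandArea], group_b: Sequence[BandArea]
) -> BandComparison:
    """Student's t-test on log10 areas; zero-area records are excluded with a warning."""
    la = np.array([b.log_area for b in group_a], dtype=float)
    lb = np.array([b.log_area for b in group_b], dtype=float)
    n_excluded = int(np.sum(~np.isfinite(la)) + np.sum(~np.isfinite(lb)))
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} record(s) with undefined (zero-area) log",
            stacklevel=2,
        )
    la = la[np.isfinite(la)]
    lb = lb[np.isfinite(lb)]
    if la.size < 2 or lb.size < 2:
        raise ValidationError("each group needs at least 2 defined log areas")
    t, p = stats.ttest_ind(la, lb, equal_var=True)
    return BandComparison(
        t=float(t),
        p=float(p),
        mean_a=float(la.mean()),
        se_a=float(la.std(ddof=1) / np.sqrt(la.size)),
        n_a=int(la.size),
        mean_b=float(lb.mean()),
        se_b=float(lb.std(ddof=1) / np.sqrt(lb.size)),
        n_b=int(lb.size),
        n_excluded=n_excluded,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate (zero-variance) input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
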