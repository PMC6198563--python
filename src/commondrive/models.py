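"""Model classes over the pipeline, in the fit()/results idiom.

Three entry points cover the two experiments:

* :class:`IntramuscularCoherence` — one subject's two-channel TA EMG record;
  ``fit()`` conditions the signals, estimates coherence/phase/cumulant with
  confidence limits, screens for cross-talk, and summarises alpha/beta areas.
* :class:`GroupCoherenceComparison` — two groups of fitted records; ``fit()``
  pools each group, runs the extended chi-squared difference-of-coherence
  test per frequency, and compares log10 band areas by Student's t.
* :class:`ReciprocalInhibition` — stimulus-locked soleus sweep sets per
  subject and state; ``fit()`` extracts M/H amplitudes in %M_max, computes
  per-subject and group suppression, and runs the mixed group-by-state ANOVA.

Each ``fit()`` returns a results object carrying the estimates and a
``summary()`` text table; plotting hangs off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandArea, BandComparison, alpha_beta_areas, compare_band_areas
from .exceptions import ValidationError
from .io import AnalysisConfig, EmgRecord, SweepSet
from .pooled import (
    CoherenceDifference,
    PooledCoherence,
    chi2_difference_test,
    pool_coherence,
    pool_cumulant,
)
from .preprocess import condition_emg
from .reflex import (
    AnovaResult,
    ReflexAmplitudes,
    SuppressionResult,
    extract_amplitudes,
    rm_anova_group_state,
    suppression_from_amplitudes,
)
from .spectral import (
    CrosstalkReport,
    CumulantDensity,
    SpectralEstimate,
    crosstalk_qc,
    cumulant_density,
    estimate_spectra,
)


# ---------------------------------------------------------------------------
# individual coherence
# ---------------------------------------------------------------------------

@dataclass
class CoherenceResults:
    """Fitted frequency- and time-domain association for one record pair."""

    estimate: SpectralEstimate
    cumulant: CumulantDensity
    crosstalk: CrosstalkReport
    band_areas: dict[str, BandArea]
    config: AnalysisConfig
    subject_id: str = ""
    group: str = ""

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Intramuscular coherence",
            "=" * 47,
            f"subject: {self.subject_id or '-'}   group: {self.group or '-'}",
            f"segments L = {e.L}, segment length T = {e.T} samples "
            f"({e.fs / e.T:.3g} Hz resolution)",
            f"coherence 95% confidence limit: {e.coh_cl:.4f}",
            f"cumulant peak: {self.cumulant.peak_lag_s * 1e3:+.1f} ms "
            f"(95% limits +/-{self.cumulant.cl_upper:.3g})",
            f"cross-talk flagged: {self.crosstalk.flagged} "
            f"(broadband fraction {self.crosstalk.broadband_fraction:.2f})",
        ]
        for name, ba in self.band_areas.items():
            log_s = f"{ba.log_area:.3f}" if ba.log_defined else "undefined"
            lines.append(
                f"{name} band {ba.band[0]:g}-{ba.band[1]:g} Hz: "
                f"area = {ba.area:.3f}, log10 = {log_s}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Coherence with its confidence limit and the cumulant density."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
        e = self.estimate
        show = e.freqs <= 60
        ax[0].plot(e.freqs[show], e.coherence[show], color="k", lw=1)
        ax[0].axhline(e.coh_cl, ls="--", color="0.4")
        ax[0].set(xlabel="frequency (Hz)", ylabel="coherence")
        c = self.cumulant
        ax[1].plot(c.lags * 1e3, c.q, color="k", lw=1)
        for y in (c.cl_upper, c.cl_lower):
            ax[1].axhline(y, ls="--", color="0.4")
        ax[1].set(xlabel="lag (ms)", ylabel="cumulant density")
        return ax


class IntramuscularCoherence:
    """Coherence analysis of one two-channel EMG record.

    Parameters
    ----------
    record : EmgRecord
        Multichannel recording holding the two channels to analyse.
    channels : pair of str
        Channel labels, default ``("TA_prox", "TA_dist")``.
    config : AnalysisConfig, optional
    band : (lo, hi) or None
        Optional band-pass applied before rectification (None for synthetic
        signals without out-of-band content).
    """

    def __init__(
        self,
        record: EmgRecord,
        channels: tuple[str, str] = ("TA_prox", "TA_dist"),
        config: AnalysisConfig | None = None,
        band: tuple[float, float] | None = None,
    ) -> None:
        self.record = record
        self.channels = channels
        self.config = config or AnalysisConfig()
        self.band = band

    def fit(self) -> CoherenceResults:
        cfg = self.config
        x = condition_emg(self.record.channel(self.channels[0]), self.record.fs, band=self.band)
        y = condition_emg(self.record.channel(self.channels[1]), self.record.fs, band=self.band)
        est = estimate_spectra(
            x, y, resolution_hz=cfg.freq_resolution_hz, alpha=cfg.confidence_alpha
        )
        cum = cumulant_density(est, max_lag_s=cfg.cumulant_lag_s)
        qc = crosstalk_qc(
            est, cum,
            broadband_threshold=cfg.qc_broadband_threshold,
            zero_lag_ms=cfg.qc_zero_lag_ms,
        )
        return CoherenceResults(
            estimate=est,
            cumulant=cum,
            crosstalk=qc,
            band_areas=alpha_beta_areas(est, cfg),
            config=cfg,
            subject_id=self.record.subject_id,
            group=self.record.group,
        )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResults:
    """Pooled coherence per group with the per-frequency chi-squared difference."""

    pooled_a: PooledCoherence
    pooled_b: PooledCoherence
    cumulant_a: CumulantDensity
    cumulant_b: CumulantDensity
    difference: CoherenceDifference
    band_tests: dict[str, BandComparison]
    labels: tuple[str, str]
    config: AnalysisConfig

    def significant_band_fraction(self, band: tuple[float, float]) -> float:
        """Fraction of bins in ``band`` (closed) where the groups differ at 5%."""
        d = self.difference
        mask = (d.freqs >= band[0]) & (d.freqs <= band[1])
        return float(np.mean(d.significant_bins[mask]))

    def summary(self) -> str:
        la, lb = self.labels
        d = self.difference
        lines = [
            "Pooled coherence comparison",
            "=" * 47,
            f"{la}: {self.pooled_a.n_records} records, "
            f"{self.pooled_a.total_segments} segments, cl = {self.pooled_a.coh_cl:.4f}",
            f"{lb}: {self.pooled_b.n_records} records, "
            f"{self.pooled_b.total_segments} segments, cl = {self.pooled_b.coh_cl:.4f}",
            f"chi2 df = {d.df}, 95% threshold = {d.threshold:.3f}",
            f"significant bins 5-15 Hz: {self.significant_band_fraction((5, 15)):.0%}; "
            f"15-35 Hz: {self.significant_band_fraction((15, 35)):.0%}",
        ]
        for name, bt in self.band_tests.items():
            lines.append(
                f"log10 {name} area: {la} {bt.mean_a:.3f} +/- {bt.se_a:.3f} (n={bt.n_a}) vs "
                f"{lb} {bt.mean_b:.3f} +/- {bt.se_b:.3f} (n={bt.n_b}); "
                f"t = {bt.t:.2f}, p = {bt.p:.3g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Pooled coherence for both groups and the chi-squared difference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
        show = self.pooled_a.freqs <= 60
        for pooled, label, color in (
            (self.pooled_a, self.labels[0], "0.5"),
            (self.pooled_b, self.labels[1], "k"),
        ):
            ax[0].plot(pooled.freqs[show], pooled.pooled_r2[show], color=color, lw=1, label=label)
            ax[0].axhline(pooled.coh_cl, ls="--", color=color, lw=0.8)
        ax[0].legend(frameon=False)
        ax[0].set(xlabel="frequency (Hz)", ylabel="pooled coherence")
        d = self.difference
        ax[1].plot(d.freqs[show], d.chi2[show], color="k", lw=1)
        ax[1].axhline(d.threshold, ls="--", color="0.4")
        ax[1].set(xlabel="frequency (Hz)", ylabel=r"$\chi^2$")
        return ax


class GroupCoherenceComparison:
    """Between-group pooled coherence comparison.

    Accepts per-group lists of :class:`EmgRecord` (fitted internally) or
    already-fitted :class:`CoherenceResults` / :class:`SpectralEstimate`.
    """

    def __init__(
        self,
        group_a: Sequence,
        group_b: Sequence,
        labels: tuple[str, str] = ("CP", "CON"),
        config: AnalysisConfig | None = None,
        band: tuple[float, float] | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        self.labels = labels
        self.band = band
        self._groups = (list(group_a), list(group_b))
        if not self._groups[0] or not self._groups[1]:
            raise ValidationError("both groups must be non-empty")

    def _as_estimates(self, group: list) -> tuple[list[SpectralEstimate], list[BandArea], list[BandArea]]:
        ests, alphas, betas = [], [], []
        for item in group:
            if isinstance(item, EmgRecord):
                item = IntramuscularCoherence(
                    item, config=self.config, band=self.band
                ).fit()
            if isinstance(item, CoherenceResults):
                ests.append(item.estimate)
                alphas.append(item.band_areas["alpha"])
                betas.append(item.band_areas["beta"])
            elif isinstance(item, SpectralEstimate):
                ests.append(item)
                areas = alpha_beta_areas(item, self.config)
                alphas.append(areas["alpha"])
                betas.append(areas["beta"])
            else:
                raise ValidationError(f"cannot interpret group item of type {type(item)}")
        return ests, alphas, betas

    def fit(self) -> GroupComparisonResults:
        ests_a, alpha_a, beta_a = self._as_estimates(self._groups[0])
        ests_b, alpha_b, beta_b = self._as_estimates(self._groups[1])
        cfg = self.config
        return GroupComparisonResults(
            pooled_a=pool_coherence(ests_a, alpha=cfg.confidence_alpha),
            pooled_b=pool_coherence(ests_b, alpha=cfg.confidence_alpha),
            cumulant_a=pool_cumulant(ests_a, max_lag_s=cfg.cumulant_lag_s),
            cumulant_b=pool_cumulant(ests_b, max_lag_s=cfg.cumulant_lag_s),
            difference=chi2_difference_test(ests_a, ests_b, alpha=cfg.confidence_alpha),
            band_tests={
                "alpha": compare_band_areas(alpha_a, alpha_b),
                "beta": compare_band_areas(beta_a, beta_b),
            },
            labels=self.labels,
            config=cfg,
        )


# ---------------------------------------------------------------------------
# functional reciprocal inhibition
# ---------------------------------------------------------------------------

@dataclass
class ReciprocalInhibitionResults:
    """Group-level H-reflex suppression with the mixed group-by-state ANOVA."""

    amplitudes: list[ReflexAmplitudes]
    table: pd.DataFrame               # subject, group, state, value (mean H %Mmax)
    m_table: pd.DataFrame             # same shape for the M-wave control
    suppression: dict[str, SuppressionResult]   # per group, from group means
    subject_suppression: pd.DataFrame  # subject, group, percent_suppression
    anova: AnovaResult | None          # None when only one group is present
    config: AnalysisConfig

    def summary(self) -> str:
        lines = [
            "Functional reciprocal inhibition",
            "=" * 47,
        ]
        for grp, sup in self.suppression.items():
            lines.append(
                f"{grp}: H-reflex {sup.rest_mean_pct:.1f} %Mmax at rest -> "
                f"{sup.onset_mean_pct:.1f} %Mmax at onset "
                f"({sup.percent_suppression:.1f}% suppression)"
            )
        if self.anova is not None:
            a = self.anova
            lines.append(
                f"group x state interaction: F({a.df1},{a.df2}) = {a.F_interaction:.2f}, "
                f"p = {a.p_interaction:.3g}"
            )
            for grp, p in a.posthoc_p.items():
                lines.append(f"  post-hoc rest vs onset in {grp}: p = {p:.3g}")
        m_means = self.m_table.groupby(["group", "state"])["value"].mean()
        lines.append(
            "M-wave control (%Mmax): "
            + ", ".join(f"{g}/{s} {v:.1f}" for (g, s), v in m_means.items())
        )
        return "\n".join(lines)


class ReciprocalInhibition:
    """H-reflex suppression analysis across subjects and groups.

    Parameters
    ----------
    trials : sequence of (subject_id, group, SweepSet)
        Each subject contributes one rest and one onset sweep set; the state
        is read from the :class:`SweepSet`.
    """

    def __init__(
        self,
        trials: Sequence[tuple[str, str, SweepSet]],
        config: AnalysisConfig | None = None,
    ) -> None:
        self.trials = list(trials)
        self.config = config or AnalysisConfig()

    def fit(self) -> ReciprocalInhibitionResults:
        amplitudes: list[ReflexAmplitudes] = []
        rows = []
        by_subject: dict[str, dict[str, ReflexAmplitudes]] = {}
        groups: dict[str, str] = {}
        for subject, group, sweeps in self.trials:
            amp = extract_amplitudes(sweeps, subject_id=subject)
            amplitudes.append(amp)
            by_subject.setdefault(subject, {})[amp.state] = amp
            groups[subject] = group
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "state": amp.state,
                    "value": float(amp.h_pct.mean()),
                    "m_value": float(amp.m_pct.mean()),
                }
            )
        frame = pd.DataFrame(rows)
        table = frame[["subject", "group", "state", "value"]]
        m_table = frame[["subject", "group", "state", "m_value"]].rename(
            columns={"m_value": "value"}
        )

        subj_rows = []
        for subject, states in by_subject.items():
            if {"rest", "onset"} <= set(states):
                sup = suppression_from_amplitudes(states["rest"], states["onset"])
                subj_rows.append(
                    {
                        "subject": subject,
                        "group": groups[subject],
                        "percent_suppression": sup.percent_suppression,
                    }
                )
        subject_suppression = pd.DataFrame(subj_rows)

        suppression: dict[str, SuppressionResult] = {}
        for grp, sub in table.groupby("group"):
            rest = sub.loc[sub["state"] == "rest", "value"].mean()
            onset = sub.loc[sub["state"] == "onset", "value"].mean()
            suppression[str(grp)] = SuppressionResult(
                rest_mean_pct=float(rest),
                onset_mean_pct=float(onset),
                percent_suppression=100.0 * (rest - onset) / rest,
            )

        anova = rm_anova_group_state(table) if table["group"].nunique() >= 2 else None
        return ReciprocalInhibitionResults(
            amplitudes=amplitudes,
            table=table,
            m_table=m_table,
            suppression=suppression,
            subject_suppression=subject_suppression,
            anova=anova,
            config=self.config,
        )
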