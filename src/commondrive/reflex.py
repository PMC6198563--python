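"""H-reflex / M-wave amplitude analysis and torque-based strength metrics.

The H-reflex indexes soleus motoneuron-pool excitability; comparing its
peak-to-peak amplitude (in % of the supramaximal M-response, M_max) at the
onset of dorsiflexion versus rest quantifies functional reciprocal inhibition.
The M-wave in the same sweeps verifies that afferent input was held constant
(target ~10% of M_max).  Torque metrics cover maximal voluntary contraction
(MVC), rate of force development over the first 200 ms (RFD200), and the
soleus/TA cocontraction index over the first second of contraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import SweepSet, TorqueTrial
from .preprocess import rectify, smooth_envelope


@dataclass
class ReflexAmplitudes:
    """Per-trial M and H peak-to-peak amplitudes for one subject and state, in %M_max."""

    subject_id: str
    state: str
    m_pct: np.ndarray
    h_pct: np.ndarray

    def __post_init__(self) -> None:
        self.m_pct = np.asarray(self.m_pct, dtype=float)
        self.h_pct = np.asarray(self.h_pct, dtype=float)
        if self.m_pct.size != self.h_pct.size:
            raise ValidationError("m_pct and h_pct must have equal length")
        if (self.m_pct < 0).any() or (self.h_pct < 0).any():
            raise ValidationError("peak-to-peak amplitudes cannot be negative")

    @property
    def n_trials(self) -> int:
        return self.m_pct.size


@dataclass
class SuppressionResult:
    """H-reflex suppression at movement onset relative to rest."""

    rest_mean_pct: float
    onset_mean_pct: float
    percent_suppression: float


@dataclass
class AnovaResult:
    """Mixed (group x state) repeated-measures ANOVA on per-subject means."""

    F_interaction: float
    df1: int
    df2: int
    p_interaction: float
    posthoc_p: dict[str, float] = field(default_factory=dict)


@dataclass
class MmaxResult:
    """Supramaximal M-response from a recruitment series."""

    m_max: float
    plateau: bool


def peak_to_peak(sweep: np.ndarray, window: tuple[float, float], fs: float) -> float:
    """Peak-to-peak amplitude (max - min) within [t_start, t_end) seconds post-stimulus."""
    sweep = np.asarray(sweep, dtype=float).ravel()
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    if not 0 <= i0 < i1 <= sweep.size:
        raise ValidationError(f"window {window} empty or outside sweep of {sweep.size} samples")
    seg = sweep[i0:i1]
    return float(seg.max() - seg.min())


def extract_amplitudes(sweeps: SweepSet, subject_id: str = "") -> ReflexAmplitudes:
    """Measure M and H peak-to-peak amplitudes of every sweep, in % of M_max."""
    m = [peak_to_peak(s, sweeps.m_window, sweeps.fs) for s in sweeps.sweeps]
    h = [peak_to_peak(s, sweeps.h_window, sweeps.fs) for s in sweeps.sweeps]
    return ReflexAmplitudes(
        subject_id=subject_id,
        state=sweeps.state,
        m_pct=100.0 * np.asarray(m) / sweeps.m_max,
        h_pct=100.0 * np.asarray(h) / sweeps.m_max,
    )


def find_mmax(
    recruitment: Sequence[tuple[float, np.ndarray]],
    fs: float | None = None,
    plateau_tol: float = 0.01,
) -> MmaxResult:
    """Supramaximal M-response from a recruitment curve of (intensity mA, sweep).

    The plateau is declared when the relative increase in peak-to-peak
    amplitude is below ``plateau_tol`` for the final two intensity steps; the
    maximum observed amplitude is returned either way (with ``plateau=False``
    and a warning when no plateau was reached).
    """
    if len(recruitment) < 3:
        raise ValidationError("need at least 3 stimulation intensities")
    intensities = [i for i, _ in recruitment]
    if any(b <= a for a, b in zip(intensities, intensities[1:])):
        raise ValidationError("intensities must be strictly increasing")
    amps = np.array(
        [np.ptp(np.asarray(s, dtype=float)) for _, s in recruitment]
    )
    rel = np.diff(amps) / np.where(amps[:-1] > 0, amps[:-1], 1.0)
    plateau = bool(np.all(rel[-2:] < plateau_tol))
    if not plateau:
        warnings.warn("M-response did not plateau; returning maximum observed amplitude",
                      stacklevel=2)
    return MmaxResult(m_max=float(amps.max()), plateau=plateau)


def percent_suppression(rest_mean: float, onset_mean: float) -> float:
    """H-reflex suppression, 100*(rest - onset)/rest; negative means facilitation."""
    if rest_mean <= 0:
        raise ValidationError("rest mean must be positive")
    return 100.0 * (rest_mean - onset_mean) / rest_mean


def suppression_from_amplitudes(
    rest: ReflexAmplitudes, onset: ReflexAmplitudes
) -> SuppressionResult:
    """Suppression computed from per-trial amplitudes of one subject."""
    rest_mean = float(rest.h_pct.mean())
    onset_mean = float(onset.h_pct.mean())
    return SuppressionResult(
        rest_mean_pct=rest_mean,
        onset_mean_pct=onset_mean,
        percent_suppression=percent_suppression(rest_mean, onset_mean),
    )


def rm_anova_group_state(table: pd.DataFrame) -> AnovaResult:
    """Mixed-design ANOVA: between-subject group, within-subject state.

    ``table`` needs columns ``subject``, ``group``, ``state``, ``value`` with
    exactly one row per subject and state.  Reports the group-by-state
    interaction F with (1, N-2) df and uncorrected paired-t post-hoc p values
    within each group.
    """
    required = {"subject", "group", "state", "value"}
    if not required.issubset(table.columns):
        raise ValidationError(f"table must have columns {sorted(required)}")
    counts = table.groupby("subject")["state"].nunique()
    if (counts != 2).any():
        raise ValidationError("every subject must have both states exactly once")
    if table.groupby("group")["subject"].nunique().min() < 2:
        raise ValidationError("need at least 2 subjects per group")

    import pingouin as pg

    with warnings.catch_warnings():
        # a zero within-subject error yields 0/0 inside the ANOVA; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(
            data=table, dv="value", within="state", subject="subject", between="group"
        )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]

    posthoc: dict[str, float] = {}
    wide = table.pivot_table(index=["group", "subject"], columns="state", values="value")
    for grp, sub in wide.groupby(level="group"):
        t, p = stats.ttest_rel(sub["rest"], sub["onset"])
        posthoc[str(grp)] = float(p)

    F = float(inter["F"])
    p = float(inter["p_unc"])
    if not np.isfinite(F):
        # zero within-subject error with zero interaction SS: no interaction
        if float(inter["SS"]) < 1e-12:
            F, p = 0.0, 1.0
        else:
            raise ValidationError("degenerate design: zero within-subject error")
    return AnovaResult(
        F_interaction=F,
        df1=int(inter["DF1"]),
        df2=int(inter["DF2"]),
        p_interaction=p,
        posthoc_p=posthoc,
    )


# ---------------------------------------------------------------------------
# torque / force metrics
# ---------------------------------------------------------------------------

def torque_onset(
    trial: TorqueTrial,
    baseline_sd_mult: float = 2.0,
    min_duration_ms: float = 10.0,
    baseline_s: float = 0.5,
) -> int:
    """Contraction onset: first sample exceeding baseline mean + k*SD for
    ``min_duration_ms`` continuously.  Requires >= 500 ms of baseline."""
    x = trial.torque
    nb = int(round(baseline_s * trial.fs))
    if x.size <= nb:
        raise ValidationError("trace too short for a 500 ms baseline")
    base = x[:nb]
    thresh = base.mean() + baseline_sd_mult * base.std()
    run = max(1, int(round(min_duration_ms / 1000.0 * trial.fs)))
    above = x > thresh
    # first index from which `run` consecutive samples are above threshold
    csum = np.concatenate([[0], np.cumsum(above)])
    windows = csum[run:] - csum[:-run]
    hits = np.flatnonzero(windows == run)
    if hits.size == 0:
        raise ValidationError("no contraction onset found")
    return int(hits[0])


def detect_countermovement(
    trial: TorqueTrial, drop_threshold: float, baseline_s: float = 0.25
) -> bool:
    """True iff torque drops below baseline by strictly more than ``drop_threshold``
    Nm anywhere before the contraction onset."""
    if trial.onset_index is None:
        raise ValidationError("trial has no onset; set onset_index or run torque_onset")
    x = trial.torque
    nb = max(1, int(round(baseline_s * trial.fs)))
    baseline = x[: min(nb, trial.onset_index or nb)].mean()
    pre = x[: trial.onset_index]
    if pre.size == 0:
        return False
    return bool((baseline - pre.min()) > drop_threshold)


def mvc_peak_torque(
    trials: Sequence[TorqueTrial],
    drop_threshold: float | None = None,
) -> tuple[int, float]:
    """Best trial index and its peak torque, excluding countermovement trials.

    ``drop_threshold`` defaults to 2% of each trial's own peak torque.
    """
    if not trials:
        raise ValidationError("need at least one trial")
    valid: list[tuple[int, float]] = []
    for i, tr in enumerate(trials):
        peak = float(tr.torque.max())
        thr = drop_threshold if drop_threshold is not None else 0.02 * peak
        if tr.onset_index is not None and detect_countermovement(tr, thr):
            continue
        valid.append((i, peak))
    if not valid:
        raise ValidationError("all trials rejected for countermovement")
    best = max(valid, key=lambda item: item[1])
    return best[0], best[1]


def rfd200(trial: TorqueTrial) -> float:
    """Rate of force development over the first 200 ms after contraction onset, Nm/s."""
    if trial.onset_index is None:
        raise ValidationError("trial has no onset_index")
    i0 = trial.onset_index
    i1 = i0 + int(round(0.2 * trial.fs))
    if i1 >= trial.torque.size:
        raise ValidationError("trace ends within 200 ms of onset")
    return (float(trial.torque[i1]) - float(trial.torque[i0])) / 0.2


def cocontraction_index(
    sol: np.ndarray,
    ta: np.ndarray,
    sol_mmax: float,
    ta_mmax: float,
    onset: int,
    fs: float,
    window_ms: float = 50.0,
) -> float:
    """Antagonist cocontraction over the first second of contraction, percent.

    Ratio of the rectified, smoothed soleus EMG area (in % of soleus M_max) to
    the rectified, smoothed TA EMG area (in % of TA M_max), onset..onset+1 s.
    """
    if sol_mmax <= 0 or ta_mmax <= 0:
        raise ValidationError("M_max values must be positive")
    n1s = int(round(1.0 * fs))
    sol = np.asarray(sol, dtype=float).ravel()
    ta = np.asarray(ta, dtype=float).ravel()
    if onset + n1s > sol.size or onset + n1s > ta.size:
        raise ValidationError("need 1000 ms of signal after onset")
    sol_env = smooth_envelope(rectify(sol), window_ms, fs)[onset : onset + n1s]
    ta_env = smooth_envelope(rectify(ta), window_ms, fs)[onset : onset + n1s]
    sol_area = float(np.sum(sol_env) / fs) / sol_mmax * 100.0
    ta_area = float(np.sum(ta_env) / fs) / ta_mmax * 100.0
    if ta_area == 0:
        raise ValidationError("zero TA area")
    return 100.0 * sol_area / ta_area
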