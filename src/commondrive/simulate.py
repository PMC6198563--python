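"""Synthetic inputs with the statistical structure the analyses assume.

Three generators are provided:

* **Common-drive EMG** — two surface-EMG channels, each the superposition of
  motor-unit action-potential (MUAP) trains from a distinct pool of units.
  Unit i on channel c fires as an inhomogeneous point process with rate

      r_i(t) = base_rate_hz * max(0, 1 + g * (kappa * s(t - d_c) + (1 - kappa) * xi_ci(t)))

  where s(t) is one shared band-limited Gaussian drive (power placed in the
  alpha/beta bands by default), xi_ci are independent band-limited noises,
  kappa in [0, 1] sets the common-drive coupling, and d_c is a per-channel
  conduction delay so genuine common drive synchronises at a non-zero lag.
  Spikes are drawn by per-sample thinning, convolved with a biphasic MUAP
  kernel (first derivative of a Gaussian, 10 ms), and summed; optional
  electrode cross-talk mixes a fraction of channel 1 into channel 2.

* **H-reflex sweep sets** — stimulus-locked soleus sweeps containing a fixed
  biphasic M-wave template (peak-to-peak drawn around 10% of M_max, emulating
  constant afferent input) and an H-reflex template whose mean amplitude drops
  by ``suppression_fraction`` at dorsiflexion onset relative to rest, with
  between-subject and trial-to-trial Gaussian variation.

* **Torque trials** — a logistic rise to peak at a given maximal slope, with
  an optional pre-onset countermovement dip and additive noise.

All randomness flows from a single integer seed: every generator builds a
``numpy.random.Generator`` from ``SeedSequence(seed)`` and draws sub-streams
through ``spawn``, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import ValidationError
from .io import EmgRecord, SweepSet, TorqueTrial

DEFAULT_DRIVE_BANDS = ((5.0, 15.0, 0.5), (15.0, 35.0, 0.5))


@dataclass
class DriveSimConfig:
    """Configuration of the two-channel common-drive EMG simulator.

    Defaults mirror the recording protocol the analyses target: 2 kHz
    sampling, 120 s static contraction, drive power split over the alpha
    (5-15 Hz) and beta (15-35 Hz) bands, ~10 Hz mean motor-unit rates, and
    channel conduction delays of 2 and 9 ms so the cumulant peak of genuine
    common drive sits clearly away from zero lag.
    """

    fs: float = 2000.0
    duration_s: float = 120.0
    n_units_per_channel: int = 40
    kappa: float = 0.4
    drive_bands: tuple = DEFAULT_DRIVE_BANDS
    base_rate_hz: float = 10.0
    modulation_depth: float = 1.0
    muap_duration_ms: float = 10.0
    channel_delays_ms: tuple[float, float] = (2.0, 9.0)
    crosstalk_coeff: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValidationError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not 0.0 <= self.crosstalk_coeff < 1.0:
            raise ValidationError(
                f"crosstalk_coeff must lie in [0, 1), got {self.crosstalk_coeff}"
            )
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("duration_s * fs must be an integer sample count")


@dataclass
class HReflexSimConfig:
    """Configuration of the H-reflex sweep-set simulator.

    Defaults emulate the control-group protocol: 15 trials per state, an
    M-response held at ~10% of M_max, a resting H-reflex around 40% of M_max
    with realistic between-subject spread, and 37% suppression of the H-reflex
    at dorsiflexion onset.  Set ``suppression_fraction=0`` for a CP-like group
    in which functional reciprocal inhibition is absent.
    """

    n_subjects: int = 15
    n_trials_per_state: int = 15
    m_target_pct: float = 10.0
    m_sd_pct: float = 1.5
    h_rest_mean_pct: float = 40.0
    h_rest_sd_pct: float = 12.0      # between-subject SD
    suppression_fraction: float = 0.37
    trial_noise_sd_pct: float = 5.0  # trial-to-trial SD within subject/state
    m_max_mv: float = 8.0
    fs: float = 2000.0
    sweep_duration_s: float = 0.08
    waveform_noise_sd_mv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_state < 1:
            raise ValidationError("n_trials_per_state must be >= 1")
        for name in ("m_sd_pct", "h_rest_sd_pct", "trial_noise_sd_pct", "waveform_noise_sd_mv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.suppression_fraction > 1.0:
            raise ValidationError("suppression_fraction cannot exceed 1")


def _band_limited_noise(
    rng: np.random.Generator,
    n_rows: int,
    n_samples: int,
    fs: float,
    bands,
) -> np.ndarray:
    """Unit-variance Gaussian noise(s) with power confined to the given bands.

    Synthesised in the frequency domain: independent complex-Gaussian Fourier
    coefficients are drawn only at in-band bins, weighted per band, and
    transformed back, so the cost scales with the occupied bandwidth.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    for lo, hi, rel_power in bands:
        in_band = (freqs >= lo) & (freqs <= hi)
        if not in_band.any():
            raise ValidationError(f"band ({lo}, {hi}) empty at fs={fs}")
        gain[in_band] = np.sqrt(rel_power / in_band.sum())
    occupied = np.flatnonzero(gain)
    coeffs = rng.standard_normal((n_rows, occupied.size, 2))
    spec = np.zeros((n_rows, freqs.size), dtype=complex)
    spec[:, occupied] = (coeffs[..., 0] + 1j * coeffs[..., 1]) * gain[occupied]
    shaped = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def muap_kernel(fs: float, duration_ms: float = 10.0) -> np.ndarray:
    """Biphasic MUAP kernel: first derivative of a Gaussian, unit peak (mV)."""
    n = max(3, int(round(duration_ms / 1000.0 * fs)))
    t = np.linspace(-3.0, 3.0, n)
    k = -t * np.exp(-0.5 * t**2)
    return k / np.abs(k).max()


def simulate_common_drive_emg(cfg: DriveSimConfig) -> EmgRecord:
    """Simulate a two-channel TA EMG record sharing a band-limited common drive.

    Returns an :class:`EmgRecord` with channels ``TA_prox`` and ``TA_dist``.
    """
    n = int(round(cfg.duration_s * cfg.fs))
    rng_drive, rng_units, rng_spikes, rng_noise = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(cfg.seed).spawn(4)
    ]

    s_drive = _band_limited_noise(rng_drive, 1, n, cfg.fs, cfg.drive_bands)[0]
    kernel = muap_kernel(cfg.fs, cfg.muap_duration_ms)
    channels = []
    for c in range(2):
        delay = int(round(cfg.channel_delays_ms[c] / 1000.0 * cfg.fs))
        s_c = np.roll(s_drive, delay)
        rates = _band_limited_noise(
            rng_units, cfg.n_units_per_channel, n, cfg.fs, cfg.drive_bands
        )
        # in-place: rates <- base * max(0, 1 + g*(kappa*s + (1-kappa)*xi)) / fs
        rates *= (1.0 - cfg.kappa)
        rates += cfg.kappa * s_c[None, :]
        rates *= cfg.modulation_depth
        rates += 1.0
        np.maximum(rates, 0.0, out=rates)
        rates *= cfg.base_rate_hz / cfg.fs
        # per-sample thinning of an inhomogeneous point process at fs
        spikes = rng_spikes.random((cfg.n_units_per_channel, n)) < rates
        amps = 0.5 + rng_units.random(cfg.n_units_per_channel)  # mV, per-unit size
        train = amps @ spikes
        emg = np.convolve(train, kernel, mode="same")
        emg += cfg.noise_sd * rng_noise.standard_normal(n)
        channels.append(emg)

    x, y = channels
    y = y + cfg.crosstalk_coeff * x
    return EmgRecord(
        samples=np.column_stack([x, y]),
        fs=cfg.fs,
        channel_labels=["TA_prox", "TA_dist"],
        subject_id="sim",
        group="CON",
        state="static",
    )


def _biphasic_template(t: np.ndarray, center_s: float, width_s: float) -> np.ndarray:
    """Gaussian-derivative wave with unit peak-to-peak amplitude."""
    z = (t - center_s) / width_s
    w = -z * np.exp(-0.5 * z**2)
    p2p = w.max() - w.min()
    return w / p2p


def simulate_hreflex_dataset(
    cfg: HReflexSimConfig,
) -> list[tuple[str, str, SweepSet]]:
    """Simulate stimulus-locked soleus sweep sets for a group of subjects.

    Returns a list of ``(subject_id, state, SweepSet)`` with states ``rest``
    and ``onset`` per subject.  The H-reflex population mean at onset is
    ``h_rest_mean_pct * (1 - suppression_fraction)``; the M-wave mean is
    ``m_target_pct`` in both states (the simulated stimulation control).
    Drawn amplitudes are floored at zero (a reflex cannot be negative).
    """
    n_samp = int(round(cfg.sweep_duration_s * cfg.fs))
    t = np.arange(n_samp) / cfg.fs
    m_shape = _biphasic_template(t, center_s=0.015, width_s=0.002)
    h_shape = _biphasic_template(t, center_s=0.038, width_s=0.003)

    ss = np.random.SeedSequence(cfg.seed)
    out: list[tuple[str, str, SweepSet]] = []
    for subj_idx, subj_seed in enumerate(ss.spawn(cfg.n_subjects)):
        rng = np.random.Generator(np.random.PCG64(subj_seed))
        h_rest_subj = max(1.0, rng.normal(cfg.h_rest_mean_pct, cfg.h_rest_sd_pct))
        for state in ("rest", "onset"):
            h_mean = h_rest_subj
            if state == "onset":
                h_mean = h_rest_subj * (1.0 - cfg.suppression_fraction)
            m_amp = np.maximum(
                0.0, rng.normal(cfg.m_target_pct, cfg.m_sd_pct, cfg.n_trials_per_state)
            )
            h_amp = np.maximum(
                0.0, rng.normal(h_mean, cfg.trial_noise_sd_pct, cfg.n_trials_per_state)
            )
            scale = cfg.m_max_mv / 100.0  # %Mmax -> mV
            sweeps = (
                m_amp[:, None] * scale * m_shape[None, :]
                + h_amp[:, None] * scale * h_shape[None, :]
                + cfg.waveform_noise_sd_mv * rng.standard_normal((cfg.n_trials_per_state, n_samp))
            )
            out.append(
                (
                    f"S{subj_idx:02d}",
                    state,
                    SweepSet(
                        sweeps=sweeps,
                        fs=cfg.fs,
                        state=state,
                        m_max=cfg.m_max_mv,
                    ),
                )
            )
    return out


def simulate_torque_trial(
    rise_rate: float,
    peak: float,
    countermovement_depth: float = 0.0,
    fs: float = 2000.0,
    seed: int = 0,
    duration_s: float = 4.0,
    onset_s: float = 1.0,
    noise_sd: float = 0.0,
) -> TorqueTrial:
    """Simulate a dorsiflexion torque trace.

    A logistic rise reaches ``peak`` Nm with maximal slope ``rise_rate`` Nm/s,
    preceded by a flat baseline (optionally dented by a countermovement dip of
    ``countermovement_depth`` Nm ~300 ms before onset).  ``onset_index`` on
    the returned trial marks where the rise leaves the baseline.
    """
    if peak <= 0:
        raise ValidationError("peak must be positive")
    if rise_rate <= 0:
        raise ValidationError("rise_rate must be positive")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    k = 4.0 * rise_rate / peak           # logistic steepness for max slope = rise_rate
    f0 = 0.005                           # onset defined at 0.5% of peak
    t_mid = onset_s + np.log((1.0 - f0) / f0) / k
    raw = peak * expit(k * (t - t_mid))
    torque = np.clip(raw - f0 * peak, 0.0, None) / (1.0 - f0)

    if countermovement_depth > 0:
        dip_center = max(0.15, onset_s - 0.3)
        torque -= countermovement_depth * np.exp(-0.5 * ((t - dip_center) / 0.05) ** 2)

    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        torque = torque + noise_sd * rng.standard_normal(n)

    return TorqueTrial(torque=torque, fs=fs, onset_index=int(round(onset_s * fs)))
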