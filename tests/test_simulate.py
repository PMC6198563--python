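"""Generator behaviour: determinism, recoverable structure, edge cases."""

import numpy as np
import pytest

from commondrive import (
    DriveSimConfig,
    HReflexSimConfig,
    IntramuscularCoherence,
    ValidationError,
    detect_countermovement,
    extract_amplitudes,
    rfd200,
    simulate_common_drive_emg,
    simulate_hreflex_dataset,
    simulate_torque_trial,
    suppression_from_amplitudes,
    torque_onset,
)


class TestCommonDriveEmg:
    def test_fixed_seed_reproduces_exactly(self):
        cfg = DriveSimConfig(duration_s=5.0, seed=42)
        a = simulate_common_drive_emg(cfg)
        b = simulate_common_drive_emg(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        a = simulate_common_drive_emg(DriveSimConfig(duration_s=5.0, seed=1))
        b = simulate_common_drive_emg(DriveSimConfig(duration_s=5.0, seed=2))
        assert not np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("bad", [{"kappa": 1.2}, {"kappa": -0.1}, {"crosstalk_coeff": 1.0}])
    def test_out_of_range_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            DriveSimConfig(**bad)

    def test_no_drive_gives_null_coherence_rate(self):
        # kappa = 0, no cross-talk: ~5% of 1-60 Hz bins above the limit
        fracs = []
        for s in range(8):
            rec = simulate_common_drive_emg(
                DriveSimConfig(duration_s=20.0, kappa=0.0, seed=900 + s)
            )
            fit = IntramuscularCoherence(rec).fit()
            e = fit.estimate
            m = (e.freqs >= 1) & (e.freqs <= 60)
            fracs.append(np.mean(e.coherence[m] > e.coh_cl))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.04)

    def test_beta_drive_raises_beta_band_only(self, driven_fit):
        e = driven_fit.estimate
        beta = (e.freqs >= 15) & (e.freqs <= 35)
        high = (e.freqs >= 45) & (e.freqs <= 60)
        assert np.mean(e.coherence[beta] > e.coh_cl) > 0.9
        assert np.mean(e.coherence[high] > e.coh_cl) < 0.3

    def test_beta_area_nondecreasing_in_coupling(self):
        # expected beta-band coherence area grows with the common-drive coupling
        means = []
        for kappa in (0.0, 0.2, 0.5, 0.8):
            areas = []
            for s in range(30):
                rec = simulate_common_drive_emg(
                    DriveSimConfig(duration_s=20.0, kappa=kappa, seed=2000 + s)
                )
                areas.append(IntramuscularCoherence(rec).fit().band_areas["beta"].area)
            means.append(np.mean(areas))
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestHReflexDataset:
    def test_zero_noise_m_wave_exact(self):
        cfg = HReflexSimConfig(
            n_subjects=2, m_sd_pct=0.0, trial_noise_sd_pct=0.0,
            waveform_noise_sd_mv=0.0, seed=3,
        )
        for subj, state, ss in simulate_hreflex_dataset(cfg):
            amp = extract_amplitudes(ss, subj)
            np.testing.assert_allclose(amp.m_pct, cfg.m_target_pct, rtol=1e-9)

    def test_no_suppression_means_equal(self):
        cfg = HReflexSimConfig(
            n_subjects=1, n_trials_per_state=2000, suppression_fraction=0.0, seed=4
        )
        data = {state: ss for _, state, ss in simulate_hreflex_dataset(cfg)}
        rest = extract_amplitudes(data["rest"]).h_pct.mean()
        onset = extract_amplitudes(data["onset"]).h_pct.mean()
        assert onset == pytest.approx(rest, rel=0.02)

    def test_suppression_recovered_at_large_n(self):
        cfg = HReflexSimConfig(
            n_subjects=2, n_trials_per_state=10_000, suppression_fraction=0.37, seed=5
        )
        by = {}
        for subj, state, ss in simulate_hreflex_dataset(cfg):
            by.setdefault(subj, {})[state] = extract_amplitudes(ss, subj)
        recovered = [
            suppression_from_amplitudes(d["rest"], d["onset"]).percent_suppression
            for d in by.values()
        ]
        assert np.mean(recovered) == pytest.approx(37.0, abs=1.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            HReflexSimConfig(m_sd_pct=-1.0)


class TestTorqueTrial:
    def test_clean_trace_monotone(self):
        tr = simulate_torque_trial(rise_rate=150.0, peak=40.0, fs=2000.0)
        assert np.all(np.diff(tr.torque) >= -1e-12)

    def test_max_slope_matches_rise_rate(self):
        tr = simulate_torque_trial(rise_rate=150.0, peak=40.0, fs=2000.0)
        slope = np.max(np.diff(tr.torque)) * 2000.0
        assert slope == pytest.approx(150.0, rel=0.01)

    def test_countermovement_detected_downstream(self):
        tr = simulate_torque_trial(
            rise_rate=150.0, peak=40.0, countermovement_depth=2.0, fs=2000.0
        )
        assert detect_countermovement(tr, drop_threshold=1.0)

    def test_deterministic_given_seed(self):
        a = simulate_torque_trial(100.0, 30.0, noise_sd=0.5, seed=9)
        b = simulate_torque_trial(100.0, 30.0, noise_sd=0.5, seed=9)
        np.testing.assert_array_equal(a.torque, b.torque)

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValidationError):
            simulate_torque_trial(rise_rate=100.0, peak=-5.0)

    def test_onset_and_rfd_recoverable_under_noise(self):
        tr = simulate_torque_trial(
            rise_rate=200.0, peak=45.0, fs=2000.0, noise_sd=0.01, seed=10
        )
        clean = simulate_torque_trial(rise_rate=200.0, peak=45.0, fs=2000.0)
        onset = torque_onset(tr)
        assert abs(onset - tr.onset_index) <= 0.010 * 2000.0  # within 10 ms
        truth = rfd200(clean)
        assert rfd200(tr) == pytest.approx(truth, rel=0.05)
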