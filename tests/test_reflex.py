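"""Reflex amplitude analysis, the mixed ANOVA, and torque metrics."""

import numpy as np
import pandas as pd
import pytest

from commondrive import (
    SweepSet,
    TorqueTrial,
    ValidationError,
    cocontraction_index,
    extract_amplitudes,
    find_mmax,
    mvc_peak_torque,
    peak_to_peak,
    percent_suppression,
    rfd200,
    rm_anova_group_state,
    torque_onset,
)

FS = 2000.0


class TestPeakToPeak:
    def test_full_sine_gives_twice_amplitude(self):
        t = np.arange(400) / FS
        sweep = np.sin(2 * np.pi * 50 * t)
        assert peak_to_peak(sweep, (0.0, 0.2), FS) == pytest.approx(2.0, rel=1e-3)

    def test_constant_sweep_is_zero(self):
        assert peak_to_peak(np.full(200, 3.3), (0.0, 0.05), FS) == 0.0

    def test_scales_linearly_with_amplitude(self):
        t = np.arange(200) / FS
        template = -((t - 0.05) / 0.005) * np.exp(-0.5 * ((t - 0.05) / 0.005) ** 2)
        amps = np.array([0.5, 1.0, 2.0, 4.0])
        p2p = [peak_to_peak(a * template, (0.0, 0.1), FS) for a in amps]
        np.testing.assert_allclose(np.array(p2p) / p2p[1], amps, rtol=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            peak_to_peak(np.zeros(100), (0.02, 0.02), FS)


class TestAmplitudeNormalisation:
    def test_common_gain_leaves_percentages_unchanged(self):
        rng = np.random.default_rng(0)
        sweeps = rng.standard_normal((5, 160))
        a = SweepSet(sweeps, FS, "rest", m_max=4.0)
        b = SweepSet(3.0 * sweeps, FS, "rest", m_max=12.0)
        np.testing.assert_allclose(
            extract_amplitudes(a).h_pct, extract_amplitudes(b).h_pct, rtol=1e-12
        )


class TestFindMmax:
    @staticmethod
    def series(amps):
        return [(float(i + 1), amp * np.array([0.0, 1.0, -1.0, 0.0])) for i, amp in enumerate(amps)]

    def test_saturating_curve_plateaus(self):
        res = find_mmax(self.series([1.0, 4.0, 7.9, 7.95, 8.0]))
        assert res.m_max == pytest.approx(2 * 8.0)
        assert res.plateau

    def test_no_plateau_warns_and_returns_max(self):
        with pytest.warns(UserWarning, match="did not plateau"):
            res = find_mmax(self.series([1.0, 2.0, 4.0, 8.0]))
        assert res.m_max == pytest.approx(2 * 8.0)
        assert not res.plateau

    def test_noisy_plateau_accepted(self):
        res = find_mmax(self.series([2.0, 6.0, 8.0, 7.96, 8.0]))
        assert res.plateau

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValidationError):
            find_mmax(self.series([1.0, 2.0]))


class TestPercentSuppression:
    def test_printed_group_means(self):
        assert percent_suppression(40.7, 25.6) == pytest.approx(37.1, abs=0.05)

    def test_no_change_is_zero(self):
        assert percent_suppression(10.0, 10.0) == 0.0

    def test_facilitation_is_negative(self):
        assert percent_suppression(40.0, 60.0) == pytest.approx(-50.0)

    def test_nonpositive_rest_rejected(self):
        with pytest.raises(ValidationError):
            percent_suppression(0.0, 5.0)


def mixed_anova_oracle(table):
    """Brute-force sums-of-squares decomposition for a balanced 2x2 mixed design."""
    y = table["value"].to_numpy()
    gm = y.mean()
    ss_total = np.sum((y - gm) ** 2)
    subj_means = table.groupby("subject")["value"].mean()
    ss_subjects = 2 * np.sum((subj_means - gm) ** 2)
    ss_group = sum(
        len(sub) * (sub["value"].mean() - gm) ** 2 for _, sub in table.groupby("group")
    )
    ss_state = sum(
        len(sub) * (sub["value"].mean() - gm) ** 2 for _, sub in table.groupby("state")
    )
    ss_cells = sum(
        len(sub) * (sub["value"].mean() - gm) ** 2
        for _, sub in table.groupby(["group", "state"])
    )
    ss_inter = ss_cells - ss_group - ss_state
    ss_error_within = ss_total - ss_subjects - ss_state - ss_inter
    n_subjects = table["subject"].nunique()
    df2 = n_subjects - 2
    return (ss_inter / 1) / (ss_error_within / df2), df2


class TestMixedAnova:
    @staticmethod
    def build_table(rest_con, onset_con, rest_cp, onset_cp):
        rows = []
        for g, rest, onset in (("CON", rest_con, onset_con), ("CP", rest_cp, onset_cp)):
            for i, (r, o) in enumerate(zip(rest, onset)):
                subj = f"{g}{i}"
                rows.append({"subject": subj, "group": g, "state": "rest", "value": r})
                rows.append({"subject": subj, "group": g, "state": "onset", "value": o})
        return pd.DataFrame(rows)

    def test_no_state_change_gives_zero_interaction(self):
        vals = [38.0, 42.0, 40.0, 45.0]
        table = self.build_table(vals, vals, vals, vals)
        res = rm_anova_group_state(table)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-9)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        table = self.build_table(
            rng.normal(40, 5, 8), rng.normal(26, 5, 8),
            rng.normal(38, 5, 8), rng.normal(38, 5, 8),
        )
        res = rm_anova_group_state(table)
        f_oracle, df2 = mixed_anova_oracle(table)
        assert res.F_interaction == pytest.approx(f_oracle, rel=1e-9)
        assert res.df1 == 1 and res.df2 == df2
        assert set(res.posthoc_p) == {"CON", "CP"}
        assert res.posthoc_p["CON"] < 0.01 < res.posthoc_p["CP"]

    def test_subject_missing_a_state_rejected(self):
        table = self.build_table([40.0, 41.0], [30.0, 31.0], [39.0, 38.0], [39.0, 38.5])
        with pytest.raises(ValidationError):
            rm_anova_group_state(table.iloc[:-1])


class TestTorqueMetrics:
    @staticmethod
    def ramp_trial(slope=100.0, n=6000, onset=2000):
        torque = np.concatenate(
            [np.zeros(onset), slope * np.arange(n - onset) / FS]
        )
        return TorqueTrial(torque=torque, fs=FS, onset_index=onset)

    def test_rfd_of_linear_ramp_is_slope(self):
        assert rfd200(self.ramp_trial(slope=123.0)) == pytest.approx(123.0, rel=1e-9)

    def test_rfd_of_flat_trace_is_zero(self):
        tr = TorqueTrial(np.zeros(6000), FS, onset_index=2000)
        assert rfd200(tr) == 0.0

    def test_rfd_needs_200ms_of_trace(self):
        tr = TorqueTrial(np.zeros(2100), FS, onset_index=2000)
        with pytest.raises(ValidationError):
            rfd200(tr)

    def test_onset_found_exactly_for_noise_free_step(self):
        tr = self.ramp_trial()
        assert torque_onset(tr) == pytest.approx(tr.onset_index, abs=1)

    def test_onset_on_pure_noise_rejected(self):
        rng = np.random.default_rng(1)
        tr = TorqueTrial(rng.standard_normal(4000) * 0.1, FS)
        with pytest.raises(ValidationError):
            torque_onset(tr, baseline_sd_mult=4.0)

    def test_mvc_argmax_and_countermovement_exclusion(self):
        peaks = [50.0, 60.0, 55.0]
        trials = [self.ramp_trial(slope=p) for p in peaks]
        idx, peak = mvc_peak_torque(trials)
        assert idx == 1
        # give the best trial a pre-onset dip: next best must win
        trials[1].torque[1000:1100] -= 5.0
        idx2, peak2 = mvc_peak_torque(trials)
        assert idx2 == 2

    def test_dip_exactly_at_threshold_not_flagged(self):
        from commondrive import detect_countermovement

        tr = self.ramp_trial()
        tr.torque[1000] = -1.0
        assert not detect_countermovement(tr, drop_threshold=1.0)
        assert detect_countermovement(tr, drop_threshold=0.999)


class TestCocontraction:
    def test_identical_normalised_signals_give_100(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000)
        assert cocontraction_index(x, x, 5.0, 5.0, onset=500, fs=FS) == pytest.approx(100.0)

    def test_ratio_arithmetic(self):
        sol = np.full(4000, 0.5)
        ta = np.full(4000, 5.0)
        # same M_max: areas 0.5 vs 5.0 -> 10%
        assert cocontraction_index(sol, ta, 8.0, 8.0, onset=500, fs=FS) == pytest.approx(10.0)

    def test_silent_antagonist_gives_zero(self):
        ta = np.full(4000, 1.0)
        assert cocontraction_index(np.zeros(4000), ta, 8.0, 8.0, 500, FS) == 0.0

    def test_zero_agonist_rejected(self):
        with pytest.raises(ValidationError):
            cocontraction_index(np.ones(4000), np.zeros(4000), 8.0, 8.0, 500, FS)
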