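import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optophys import evoked as evk
from optophys import protocols as prot
from optophys import synthetic as syn
from optophys.core import (
    DEPRESSED,
    NON_MODULATED,
    POTENTIATED,
    LfpTrace,
    SpikeTrain,
)
from optophys.errors import InsufficientDataError, InvalidParameterError


def make_trials(pre, post, fs=1000.0, t_pre0=0.0, t_post0=1800.0, spacing=5.0):
    """Build an EvokedTrialMatrix directly from per-phase snippet stacks."""
    trials = np.concatenate([pre, post]) if len(post) else np.asarray(pre)
    times = np.concatenate(
        [t_pre0 + spacing * np.arange(len(pre)), t_post0 + spacing * np.arange(len(post))]
    )
    phase = np.array(["Pre"] * len(pre) + ["Post"] * len(post))
    return evk.EvokedTrialMatrix(trials, times, phase, trials.shape[1] // 2, fs)


def kernel_snippets(n, amp, noise_sd, rng, n_side=100):
    """Snippets with the default biphasic kernel after onset plus noise."""
    k = syn.default_evoked_kernel(1000.0)
    snip = np.zeros((n, 2 * n_side))
    snip[:, n_side : n_side + k.size] = amp * k
    if noise_sd:
        snip += rng.normal(0, noise_sd, snip.shape)
    return snip


class TestExtractTrials:
    def test_full_session_count(self):
        sched = prot.build_test_pulses(3600.0)
        gt = syn.EvokedGroundTruth(10.0, 10.0, background_sd=0.0)
        lfp = syn.generate_evoked_lfp(gt, sched, 3600.0, seed=0)
        with pytest.warns(UserWarning):
            # 720 pulses over the hour; the first (t = 0) lacks its 100 ms
            # pre-window and is dropped
            trials = evk.extract_trials(lfp, sched, 1800.0)
        assert trials.n_trials == 719
        assert np.sum(trials.phase == "Pre") == 359
        assert np.sum(trials.phase == "Post") == 360

    def test_edge_pulse_dropped(self):
        lfp = LfpTrace(np.zeros(2000), 1000.0)
        sched = prot.StimSchedule(np.array([0.05, 1.0]), 0.015)
        with pytest.warns(UserWarning):
            trials = evk.extract_trials(lfp, sched, 10.0)
        assert trials.n_trials == 1
        assert trials.trial_times[0] == 1.0

    def test_block_pulses_excluded(self):
        sched = prot.StimSchedule(
            np.arange(0.5, 100.0, 5.0),
            0.015,
            block_boundaries=[(40.0, 60.0)],
        )
        lfp = LfpTrace(np.zeros(100_000), 1000.0)
        trials = evk.extract_trials(lfp, sched, 50.0)
        assert not np.any((trials.trial_times >= 40.0) & (trials.trial_times < 60.0))

    def test_phase_assignment(self):
        sched = prot.StimSchedule(np.array([1.0, 5.0]), 0.015)
        lfp = LfpTrace(np.zeros(10_000), 1000.0)
        trials = evk.extract_trials(lfp, sched, 3.0)
        assert list(trials.phase) == ["Pre", "Post"]

    def test_block_exclusion_preserves_pre_stats(self, rng):
        # excluding pulses inside a post-phase protocol block must not touch
        # Pre-phase amplitudes
        n = 40_000
        lfp = LfpTrace(rng.normal(0, 1, n), 1000.0)
        base = prot.StimSchedule(np.arange(0.5, 40.0, 1.0), 0.015)
        blocked = prot.StimSchedule(
            base.onsets.copy(), 0.015, block_boundaries=[(30.0, 35.0)]
        )
        t_pre = evk.trial_amplitudes(
            evk.extract_trials(lfp, base, 20.0).select("Pre")
        )
        t_pre_blocked = evk.trial_amplitudes(
            evk.extract_trials(lfp, blocked, 20.0).select("Pre")
        )
        assert np.allclose(t_pre, t_pre_blocked)


class TestPeakToPeak:
    def test_sine_cycle(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        assert evk.peak_to_peak(3.0 * np.sin(2 * np.pi * t)) == pytest.approx(6.0, rel=1e-4)

    def test_constant_zero(self):
        assert evk.peak_to_peak(np.full(100, 2.5)) == 0.0

    def test_linear_ramp(self):
        assert evk.peak_to_peak(np.linspace(-2.0, 5.0, 50)) == pytest.approx(7.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            evk.peak_to_peak(np.array([]))

    @given(
        offset=st.floats(min_value=-100, max_value=100),
        gain=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=30, deadline=None)
    def test_offset_invariant_gain_linear(self, offset, gain):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 1, 200)
        base = evk.peak_to_peak(w)
        assert evk.peak_to_peak(w + offset) == pytest.approx(base, rel=1e-9)
        assert evk.peak_to_peak(gain * w) == pytest.approx(gain * base, rel=1e-9)


class TestWireResponsiveness:
    def test_noise_free_kernel_responsive(self, rng):
        trials = make_trials(kernel_snippets(20, 5.0, 0.0, rng), np.empty((0, 200)))
        assert evk.wire_is_responsive(trials)

    def test_too_few_trials(self, rng):
        trials = make_trials(kernel_snippets(1, 5.0, 0.0, rng), np.empty((0, 200)))
        with pytest.raises(InsufficientDataError):
            evk.wire_is_responsive(trials)

    def test_null_rate_close_to_one_sided_alpha(self, rng):
        # pure-noise trials: p < alpha AND post > pre happens ~alpha/2
        n_sims, hits = 400, 0
        for _ in range(n_sims):
            snips = rng.normal(0, 1, (30, 200))
            trials = make_trials(snips, np.empty((0, 200)))
            hits += evk.wire_is_responsive(trials)
        rate = hits / n_sims
        assert rate <= 0.025 + 3 * np.sqrt(0.025 * 0.975 / n_sims)

    def test_power_monotone_in_snr(self, rng):
        rates = []
        for amp in (0.5, 2.0, 8.0):
            hits = 0
            for _ in range(50):
                trials = make_trials(
                    kernel_snippets(30, amp, 1.0, rng), np.empty((0, 200))
                )
                hits += evk.wire_is_responsive(trials)
            rates.append(hits / 50)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0


class TestAmplitudeTimecourse:
    def test_constant_amplitude_flat_100(self, rng):
        pre = kernel_snippets(60, 5.0, 0.0, rng)
        post = kernel_snippets(60, 5.0, 0.0, rng)
        trials = make_trials(pre, post, t_pre0=0.0, t_post0=300.0)
        tc = evk.amplitude_timecourse(trials)
        assert np.allclose(tc.values[np.isfinite(tc.values)], 100.0)

    @pytest.mark.parametrize("ratio,expected", [(1.4, 140.0), (0.5, 50.0)])
    def test_ratio_recovery(self, rng, ratio, expected):
        # low white noise: per-trial peak-to-peak stays essentially unbiased
        pre = kernel_snippets(120, 5.0, 0.1, rng)
        post = kernel_snippets(120, 5.0 * ratio, 0.1, rng)
        trials = make_trials(pre, post, t_pre0=0.0, t_post0=600.0)
        tc = evk.amplitude_timecourse(trials)
        post_mask = tc.bin_edges[:-1] >= 600.0
        vals = tc.values[post_mask]
        assert np.nanmean(vals) == pytest.approx(expected, rel=0.1)


class TestClassifyLfp:
    def _session_trials(self, ratio, noise, rng, n_per_phase=360):
        pre = kernel_snippets(n_per_phase, 5.0, noise, rng)
        post = kernel_snippets(n_per_phase, 5.0 * ratio, noise, rng)
        return make_trials(pre, post, t_pre0=0.0, t_post0=1800.0)

    def test_identical_bins_non_modulated(self, rng):
        trials = self._session_trials(1.0, 0.0, rng)
        call = evk.classify_lfp(trials)
        assert call.label == NON_MODULATED

    def test_potentiation_150(self, rng):
        call = evk.classify_lfp(self._session_trials(1.5, 0.5, rng), n_comparisons=10)
        assert call.label == POTENTIATED

    def test_depression_50(self, rng):
        call = evk.classify_lfp(self._session_trials(0.5, 0.5, rng), n_comparisons=10)
        assert call.label == DEPRESSED

    def test_null_calibration(self, rng):
        n_sims, n_comp, hits = 100, 10, 0
        for _ in range(n_sims):
            call = evk.classify_lfp(
                self._session_trials(1.0, 1.0, rng, n_per_phase=360),
                n_comparisons=n_comp,
            )
            hits += call.label != NON_MODULATED
        alpha_corr = 0.05 / n_comp
        assert hits / n_sims <= alpha_corr + 3 * np.sqrt(
            alpha_corr * (1 - alpha_corr) / n_sims
        )


class TestEvokedFiring:
    def test_no_spikes_not_modulated(self):
        train = SpikeTrain("u", np.array([]), (0.0, 1800.0))
        sched = prot.build_test_pulses(1800.0)
        res = evk.evoked_firing(train, sched)
        assert res.label == evk.NOT_MODULATED
        assert res.p_value == 1.0

    def test_bump_is_activated(self):
        sched = prot.build_test_pulses(1800.0)
        gt = syn.UnitGroundTruth(4.0, 1.0, evoked_bump=(0.0, 0.015, 40.0))
        train = syn.generate_spike_train(gt, 1800.0, 7, schedule=sched)
        res = evk.evoked_firing(train, sched)
        assert res.label == evk.ACTIVATED
        assert res.on_rates.mean() > res.off_rates.mean()

    def test_null_rate_close_to_alpha(self):
        sched = prot.build_test_pulses(1800.0)
        hits = 0
        n_sims = 150
        for seed in range(n_sims):
            train = syn.generate_spike_train(
                syn.UnitGroundTruth(4.0, 1.0), 1800.0, seed
            )
            hits += evk.evoked_firing(train, sched).label != evk.NOT_MODULATED
        assert hits / n_sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestEvokedFiringTimecourse:
    def test_stationary_flat_non_modulated(self):
        sched = prot.build_test_pulses(3600.0)
        gt = syn.UnitGroundTruth(4.0, 1.0, evoked_bump=(0.0, 0.02, 60.0))
        train = syn.generate_spike_train(gt, 3600.0, 9, schedule=sched)
        tc, call = evk.evoked_firing_timecourse(train, sched, 1800.0)
        assert call.label == NON_MODULATED
        assert np.nanmean(tc.values) == pytest.approx(100.0, rel=0.2)

    def test_gain_doubling_potentiated(self):
        sched = prot.build_test_pulses(3600.0)
        # evoked response bump doubles after the manipulation
        gt_pre = syn.UnitGroundTruth(4.0, 1.0, evoked_bump=(0.0, 0.02, 40.0))
        gt_post = syn.UnitGroundTruth(4.0, 1.0, evoked_bump=(0.0, 0.02, 80.0))
        pre = syn.generate_spike_train(gt_pre, 1800.0, 10, schedule=sched)
        post = syn.generate_spike_train(gt_post, 1800.0, 11, schedule=sched)
        spikes = np.concatenate([pre.spike_times, post.spike_times + 1800.0])
        train = SpikeTrain("u", spikes, (0.0, 3600.0))
        tc, call = evk.evoked_firing_timecourse(train, sched, 1800.0)
        assert call.label == POTENTIATED
        post_vals = tc.values[tc.bin_edges[:-1] >= 1800.0]
        # ON rate = baseline 4 Hz + bump (40 -> 80 Hz for 20 of 25 ms)
        on_pre = 4.0 + 40.0 * 0.02 / 0.025
        on_post = 4.0 + 80.0 * 0.02 / 0.025
        assert np.nanmean(post_vals) == pytest.approx(100 * on_post / on_pre, rel=0.1)
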