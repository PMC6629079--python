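"""Synthetic oddball EEG generator: trial order, waveform composition,
determinism and cohort-level parameter draws."""

import numpy as np
import pytest

from oddballeeg.montage import DEFAULT_SCALP_64
from oddballeeg.preprocess import (average_epochs, baseline_correct,
                                   rereference_average)
from oddballeeg.simulate import (GroupSpec, PRESETS, SimulationParams,
                                 default_group_specs, simulate_cohort,
                                 simulate_epochs, simulate_trial_sequence)


def no_adjacent_targets(seq):
    return all(not (a == b == "target") for a, b in zip(seq, seq[1:]))


class TestTrialSequence:
    def test_oddball_structure(self):
        seq = simulate_trial_sequence(50, 150, seed=1)
        assert len(seq) == 200
        assert seq.count("target") == 50
        assert no_adjacent_targets(seq)

    def test_no_targets(self):
        assert simulate_trial_sequence(0, 5, seed=0) == ["standard"] * 5

    @pytest.mark.parametrize("seed", range(10))
    def test_adjacency_exhaustive_scan(self, seed):
        seq = simulate_trial_sequence(3, 3, seed=seed)
        assert seq.count("target") == 3 and seq.count("standard") == 3
        for i in range(len(seq) - 1):
            assert not (seq[i] == "target" and seq[i + 1] == "target")

    def test_infeasible_counts_raise(self):
        with pytest.raises(ValueError, match="non-adjacent"):
            simulate_trial_sequence(4, 2, seed=0)
        # boundary n_target == n_standard + 1 is feasible (alternating)
        assert simulate_trial_sequence(3, 2, seed=0) == \
            ["target", "standard"] * 2 + ["target"]

    def test_reproducible_under_seed(self):
        assert simulate_trial_sequence(50, 150, 7) == \
            simulate_trial_sequence(50, 150, 7)
        assert simulate_trial_sequence(50, 150, 7) != \
            simulate_trial_sequence(50, 150, 8)


class TestSimulateEpochs:
    def test_effects_off_gives_pure_weighted_sinusoid(self):
        p = SimulationParams(seed=2, noise_sd=0.0, p3_amplitude=0.0,
                             erd_depth=0.0, n_target=5, n_standard=15)
        epochs, _ = simulate_epochs(p)
        w = p.resolved_alpha_topography()
        ref = epochs.ch_names.index("POz")  # unit alpha weight
        for i in range(epochs.n_trials):
            carrier = epochs.data[i, ref, :]
            # every scalp channel is the carrier scaled by its alpha weight
            assert np.allclose(epochs.data[i, :-1, :],
                               w[:, None] * carrier[None, :], atol=1e-12)
            # sinusoid of the configured amplitude (the sample grid can
            # miss the crest by up to half a sample: factor cos(pi*f/fs))
            assert np.abs(carrier).max() == pytest.approx(
                p.alpha_amplitude, rel=1.0 - np.cos(np.pi * 10.0 / 500.0))

    def test_noise_free_average_peak_matches_injection(self):
        p = SimulationParams(seed=3, noise_sd=0.0, p3_amplitude=10.0,
                             p3_latency=400.0)
        epochs, _ = simulate_epochs(p)
        avg = epochs.data[:, :-1, :].mean(axis=0)
        k = int(np.argmax(p.resolved_p3_topography()))
        assert DEFAULT_SCALP_64[k] == "Pz"
        s = int(np.argmax(avg[k]))
        assert abs(epochs.times[s] - 400.0) <= 2.0  # within one sample
        assert avg[k, s] == pytest.approx(10.0, abs=1e-9)

    def test_prestimulus_contains_no_p3(self):
        p = SimulationParams(seed=3, noise_sd=0.0, p3_amplitude=10.0,
                             erd_depth=0.0)
        epochs, _ = simulate_epochs(p)
        pre = epochs.times < 0
        k = epochs.ch_names.index("Pz")
        avg = epochs.data[:, k, pre].mean(axis=0)
        assert np.abs(avg).max() < 1e-9  # carrier cancels, no transient

    def test_deterministic_under_seed(self):
        a, ta = simulate_epochs(SimulationParams(seed=11, n_target=8,
                                                 n_standard=24))
        b, tb = simulate_epochs(SimulationParams(seed=11, n_target=8,
                                                 n_standard=24))
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta.rts, tb.rts)
        assert ta.trial_labels == tb.trial_labels

    def test_p3_amplitude_scales_average_linearly(self):
        peaks = []
        for amp in (5.0, 10.0):
            p = SimulationParams(seed=4, noise_sd=0.0, p3_amplitude=amp)
            epochs, _ = simulate_epochs(p)
            ev = average_epochs(baseline_correct(epochs))
            peaks.append(ev.data[epochs.ch_names.index("Pz")].max())
        assert peaks[1] == pytest.approx(2.0 * peaks[0], rel=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="erd_depth"):
            SimulationParams(erd_depth=1.4)
        with pytest.raises(ValueError, match="p3_latency"):
            SimulationParams(p3_latency=1200.0)
        with pytest.raises(ValueError, match="non-negative"):
            SimulationParams(noise_sd=-1.0)

    def test_blinks_reach_veog_and_frontal_channels(self):
        p = SimulationParams(seed=9, noise_sd=0.0, blink_rate=2.0,
                             n_target=10, n_standard=30)
        epochs, truth = simulate_epochs(p)
        assert any(len(b) > 0 for b in truth.blink_samples)
        veog = epochs.data[:, -1, :]
        # at least one full-amplitude blink (overlapping blinks may sum)
        assert np.abs(veog).max() >= 0.9 * 150.0
        # frontal sites pick up more blink than parietal ones
        fp = epochs.ch_names.index("Fpz")
        pz = epochs.ch_names.index("Pz")
        blink_trials = [i for i, b in enumerate(truth.blink_samples) if b]
        assert np.abs(epochs.data[blink_trials, fp, :]).max() > \
            np.abs(epochs.data[blink_trials, pz, :]).max()


class TestLatencyRecovery:
    def test_noise_free_recovery_is_sample_exact(self):
        from oddballeeg.erp import find_p3
        for seed in range(10):
            p = SimulationParams(seed=seed, noise_sd=0.0, p3_latency=400.0,
                                 n_target=30, n_standard=90)
            epochs, truth = simulate_epochs(p)
            ev = average_epochs(baseline_correct(epochs))
            assert abs(find_p3(ev).latency_ms - truth.p3_latency) <= 4.0

    def test_noisy_recovery_within_peak_picking_jitter(self):
        # at noise one quarter of the alpha amplitude, raw argmax
        # peak-picking of the broad P3 carries a few ms of jitter; the
        # error stays within +-8 ms (4 samples) in >=95% of runs
        from oddballeeg.erp import find_p3
        hits = 0
        for seed in range(100):
            p = SimulationParams(seed=seed, noise_sd=1.0, alpha_amplitude=4.0,
                                 n_target=30, n_standard=90, p3_latency=400.0)
            epochs, truth = simulate_epochs(p)
            ev = average_epochs(baseline_correct(rereference_average(epochs)))
            hits += abs(find_p3(ev).latency_ms - truth.p3_latency) <= 8.0
        assert hits >= 95


class TestSimulateCohort:
    def test_group_mean_injected_rts_match_presets(self):
        members = simulate_cohort(n_per_group=10, seed=1)
        assert len(members) == 30
        for spec in default_group_specs():
            rts = [np.mean(m.truth.rts) for m in members
                   if m.group == spec.name]
            sem = spec.rt_sd / np.sqrt(len(rts))
            assert abs(np.mean(rts) - spec.rt_mean) <= 2.0 * sem + 5.0

    def test_zero_between_subject_sd_pins_group_means(self):
        members = simulate_cohort(n_per_group=1, seed=3,
                                  between_subject_scale=0.0)
        for m in members:
            spec = PRESETS[m.group]
            assert m.truth.p3_latency == pytest.approx(spec.p3_lat_mean)
            assert m.truth.erd_latency == pytest.approx(spec.erd_lat_mean)
            assert m.truth.erd_depth == pytest.approx(spec.erd_depth_mean)

    def test_requires_a_group(self):
        with pytest.raises(ValueError, match="at least one group"):
            simulate_cohort(group_specs=[], n_per_group=2)

    def test_cohort_deterministic(self):
        a = simulate_cohort(n_per_group=2, seed=5)
        b = simulate_cohort(n_per_group=2, seed=5)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.epochs.data, mb.epochs.data)
            assert ma.truth.p3_latency == mb.truth.p3_latency
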