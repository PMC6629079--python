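"""Preprocessing chain: average reference, baseline, EOG regression,
amplitude rejection and minimum-trial averaging."""

import numpy as np
import pytest

from conftest import build_epochs
from oddballeeg.containers import EOG, SCALP
from oddballeeg.preprocess import (InsufficientTrialsError, average_epochs,
                                   baseline_correct, preprocess_pipeline,
                                   regress_eog, reject_artifacts,
                                   rereference_average)
from oddballeeg.simulate import SimulationParams, simulate_epochs


class TestRereference:
    def test_zero_mean_pair_unchanged(self):
        ep = build_epochs(np.array([[[3.0, 3.0], [-3.0, -3.0]]]))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data, ep.data)

    def test_subtracts_instantaneous_mean(self):
        ep = build_epochs(np.array([[[5.0, 5.0], [1.0, 1.0]]]))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data[0, :, 0], [2.0, -2.0])

    def test_scalp_mean_vanishes_on_random_data(self, rng):
        ep = build_epochs(rng.normal(size=(4, 64, 30)))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)

    def test_eog_channel_untouched(self, rng):
        data = rng.normal(size=(2, 3, 10))
        ep = build_epochs(data, ch_roles=[SCALP, SCALP, EOG])
        out = rereference_average(ep)
        np.testing.assert_array_equal(out.data[:, 2, :], data[:, 2, :])

    def test_single_scalp_channel_rejected(self, rng):
        ep = build_epochs(rng.normal(size=(1, 2, 5)),
                          ch_roles=[SCALP, EOG])
        with pytest.raises(ValueError, match="at least 2 scalp"):
            rereference_average(ep)

    def test_idempotent(self, rng):
        ep = build_epochs(rng.normal(size=(3, 8, 20)))
        once = rereference_average(ep)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        ep = build_epochs(np.full((1, 2, 450), 7.0))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_ramp_shifts_by_baseline_mean(self, epoch_times):
        ramp = np.tile(epoch_times, (1, 2, 1))
        ep = build_epochs(ramp)
        out = baseline_correct(ep, (-100.0, 0.0))
        m = epoch_times[(epoch_times >= -100) & (epoch_times <= 0)].mean()
        np.testing.assert_allclose(out.data, ramp - m, atol=1e-9)

    def test_recomputed_baseline_mean_is_zero(self, rng):
        ep = build_epochs(rng.normal(size=(5, 6, 450)))
        out = baseline_correct(ep)
        sl = out.window_slice((-100.0, 0.0))
        np.testing.assert_allclose(out.data[:, :, sl].mean(axis=2), 0.0,
                                   atol=1e-9)

    def test_interval_outside_epoch_rejected(self, rng):
        ep = build_epochs(rng.normal(size=(1, 2, 450)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (-500.0, -200.0))

    def test_commutes_with_averaging(self, rng):
        ep = build_epochs(rng.normal(size=(20, 4, 450)))
        a = average_epochs(baseline_correct(ep))
        b = baseline_correct(ep)  # average then baseline, by hand
        avg = ep.data.mean(axis=0)
        sl = ep.window_slice((-100.0, 0.0))
        avg_then_base = avg - avg[:, sl].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(a.data, avg_then_base, atol=1e-9)


class TestEogRegression:
    def test_perfectly_coupled_scalp_zeroed(self, rng):
        eog = rng.normal(size=(3, 1, 100))
        data = np.concatenate([0.5 * eog, eog], axis=1)
        ep = build_epochs(data, ch_names=["C1", "VEOG"],
                          ch_roles=[SCALP, EOG])
        out = regress_eog(ep, "VEOG")
        np.testing.assert_allclose(out.data[:, 0, :], 0.0, atol=1e-9)

    def test_zero_eog_is_noop_with_warning(self, rng):
        data = rng.normal(size=(2, 3, 40))
        data[:, 2, :] = 0.0
        ep = build_epochs(data, ch_roles=[SCALP, SCALP, EOG])
        with pytest.warns(RuntimeWarning, match="zero variance"):
            out = regress_eog(ep, "ch2")
        np.testing.assert_array_equal(out.data, ep.data)

    def test_simulated_blinks_decorrelated(self):
        p = SimulationParams(seed=21, noise_sd=2.0, blink_rate=1.0,
                             n_target=20, n_standard=60)
        epochs, _ = simulate_epochs(p)
        out = regress_eog(epochs, "VEOG")
        eog = out.data[:, -1, :].ravel()
        for k in (out.ch_names.index("Fpz"), out.ch_names.index("Cz")):
            r = np.corrcoef(out.data[:, k, :].ravel(), eog)[0, 1]
            assert abs(r) < 0.01


class TestRejection:
    def test_exceeding_trial_rejected(self):
        data = np.zeros((1, 2, 10))
        data[0, 0, 3] = 80.0
        out, n = reject_artifacts(build_epochs(data))
        assert n == 1 and out.rejected[0]

    def test_boundary_value_kept(self):
        data = np.zeros((1, 2, 10))
        data[0, 1, 5] = -75.0
        out, n = reject_artifacts(build_epochs(data))
        assert n == 0 and not out.rejected[0]

    def test_matches_per_sample_scan(self, rng):
        data = rng.normal(scale=40.0, size=(100, 8, 50))
        ep = build_epochs(data)
        out, n = reject_artifacts(ep, threshold=75.0)
        expected = np.array([any(abs(data[t, c, s]) > 75.0
                                 for c in range(8) for s in range(50))
                             for t in range(100)])
        np.testing.assert_array_equal(out.rejected, expected)
        assert n == expected.sum()
        assert n + (~out.rejected).sum() == 100

    def test_mask_monotone_in_threshold(self, rng):
        ep = build_epochs(rng.normal(scale=40.0, size=(60, 4, 40)))
        strict, _ = reject_artifacts(ep, threshold=60.0)
        loose, _ = reject_artifacts(ep, threshold=90.0)
        assert set(np.flatnonzero(loose.rejected)) <= \
            set(np.flatnonzero(strict.rejected))

    def test_eog_channel_ignored(self):
        data = np.zeros((1, 2, 10))
        data[0, 1, 0] = 200.0  # huge blink on the EOG channel only
        ep = build_epochs(data, ch_roles=[SCALP, EOG])
        # needs >= 2 scalp? rejection does not re-reference; single scalp ok
        out, n = reject_artifacts(ep)
        assert n == 0


class TestAveraging:
    def test_too_few_trials_error_names_count(self, rng):
        ep = build_epochs(rng.normal(size=(14, 2, 20)))
        with pytest.raises(InsufficientTrialsError, match="14"):
            average_epochs(ep)

    def test_identical_trials_average_to_one(self, rng):
        trial = rng.normal(size=(1, 3, 25))
        ep = build_epochs(np.repeat(trial, 20, axis=0))
        out = average_epochs(ep)
        np.testing.assert_allclose(out.data, trial[0], atol=1e-12)
        assert out.n_trials_averaged == 20

    def test_matches_independent_mean(self, rng):
        data = rng.normal(size=(30, 4, 40))
        ep = build_epochs(data)
        out = average_epochs(ep)
        np.testing.assert_allclose(out.data, data.mean(axis=0), atol=1e-12)

    def test_rejected_and_incorrect_trials_excluded(self, rng):
        data = rng.normal(size=(20, 2, 10))
        correct = np.ones(20, bool)
        correct[0] = False
        ep = build_epochs(data, correct=correct)
        ep.rejected[1] = True
        out = average_epochs(ep)
        assert out.n_trials_averaged == 18
        np.testing.assert_allclose(out.data, data[2:].mean(axis=0),
                                   atol=1e-12)


class TestPipelineOrder:
    def test_counts_are_consistent(self):
        p = SimulationParams(seed=5, noise_sd=2.0, n_target=40,
                             n_standard=120)
        epochs, _ = simulate_epochs(p)
        clean, evoked, stats = preprocess_pipeline(epochs)
        assert stats["n_targets"] == 40
        assert stats["n_averaged"] == evoked.n_trials_averaged
        assert stats["n_averaged"] <= stats["n_targets"] - \
            stats["n_incorrect_targets"]
        sl = clean.window_slice((-100.0, 0.0))
        np.testing.assert_allclose(clean.data[:, :, sl].mean(axis=2), 0.0,
                                   atol=1e-9)
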