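"""Dopamine signal and learning rules: gating, scaling and boundedness."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from habitloops import (DEFAULT_PARAMS, DopamineSignal, Network, Projection,
                        RateUnitPopulation, build_model, build_task,
                        da_deviation, phasic_dopamine, preset, run_subject,
                        update_corticostriatal, update_shortcut)
from habitloops.network import ConfigurationError


def make_proj(W, plastic=True, tau_w=15000.0, w_min=0.0, w_max=np.inf):
    net = Network()
    src = net.add(RateUnitPopulation("pre", W.shape[1]))
    tgt = net.add(RateUnitPopulation("post", W.shape[0]))
    return Projection("p", src, tgt, W, plastic=plastic, tau_w=tau_w,
                      w_min=w_min, w_max=w_max)


class TestPhasicDopamine:
    def test_reward_burst_reaches_peak(self):
        da = DopamineSignal(tonic=0.1, peak=1.0)
        assert phasic_dopamine(True, da) == 1.0
        assert da_deviation(da) == pytest.approx(0.9)

    def test_zero_amplitude_means_zero_deviation(self):
        da = DopamineSignal(tonic=0.6, peak=0.6)
        phasic_dopamine(True, da)
        assert da_deviation(da) == 0.0
        phasic_dopamine(False, da)
        assert da_deviation(da) == 0.0

    def test_omission_dip(self):
        # dip amplitude 0.1: level floors at tonic - dip
        da = DopamineSignal(tonic=0.1, peak=0.2, dip_fraction=1.0)
        assert phasic_dopamine(False, da) == 0.0
        assert da_deviation(da) == pytest.approx(-0.1)

    def test_dip_level_never_negative(self):
        da = DopamineSignal(tonic=0.1, peak=2.0, dip_fraction=1.0)
        assert phasic_dopamine(False, da) == 0.0


class TestCorticostriatalRule:
    def test_hand_computed_single_synapse(self):
        """Scalar oracle: dW = lr*dev*(post-theta)*pre*(kappa*post - W)."""
        lr, dev, pre, post, theta, kappa, w0 = 0.2, 0.9, 1.0, 0.8, 0.1, 1.5, 0.3
        proj = make_proj(np.array([[w0]]))
        update_corticostriatal(proj, np.array([pre]), np.array([post]), dev,
                               "d1", lr, post_threshold=theta,
                               soft_bound_gain=kappa)
        expected = w0 + lr * dev * (post - theta) * pre * (kappa * post - w0)
        assert proj.W[0, 0] == pytest.approx(expected)

    def test_depression_is_linear(self):
        lr, dev, pre, post, theta, w0 = 0.2, -0.3, 1.0, 0.8, 0.1, 0.5
        proj = make_proj(np.array([[w0]]))
        update_corticostriatal(proj, np.array([pre]), np.array([post]), dev,
                               "d1", lr, post_threshold=theta)
        assert proj.W[0, 0] == pytest.approx(w0 + lr * dev * (post - theta) * pre)

    def test_d2_sign_is_opposite(self):
        w0 = 0.5
        p1 = make_proj(np.array([[w0]]))
        p2 = make_proj(np.array([[w0]]))
        update_corticostriatal(p1, np.ones(1), np.ones(1), 0.4, "d1", 0.1)
        update_corticostriatal(p2, np.ones(1), np.ones(1), 0.4, "d2", 0.1)
        assert p1.W[0, 0] > w0        # burst potentiates direct pathway
        assert p2.W[0, 0] < w0        # burst depresses indirect pathway

    def test_noop_when_dopamine_at_baseline(self):
        proj = make_proj(np.full((2, 3), 0.4))
        update_corticostriatal(proj, np.ones(3), np.ones(2), 0.0, "d1", 0.5)
        np.testing.assert_array_equal(proj.W, 0.4)

    def test_noop_without_presynaptic_activity(self):
        proj = make_proj(np.full((2, 3), 0.4))
        update_corticostriatal(proj, np.zeros(3), np.ones(2), 0.9, "d1", 0.5)
        np.testing.assert_array_equal(proj.W, 0.4)

    def test_noop_with_zero_plasticity_gain(self):
        proj = make_proj(np.full((2, 3), 0.4))
        update_corticostriatal(proj, np.ones(3), np.ones(2), 0.9, "d1", 0.5,
                               plasticity_gain=0.0)
        np.testing.assert_array_equal(proj.W, 0.4)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_weights_stay_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        proj = make_proj(rng.uniform(0, 1, (3, 4)), w_min=0.1, w_max=1.0)
        for _ in range(30):
            update_corticostriatal(
                proj, rng.uniform(0, 2, 4), rng.uniform(0, 2, 3),
                rng.uniform(-1, 1), rng.choice(["d1", "d2"]), 0.5)
        assert (proj.W >= 0.1).all() and (proj.W <= 1.0).all()


class TestShortcutRule:
    def test_per_step_change_scales_inversely_with_tau(self):
        """Identical rate history: |dW| ratio between tau 6000 and 15000 is
        exactly 15000/6000 = 2.5."""
        pre, post = np.array([1.0, 0.0]), np.array([0.8])
        w0 = np.array([[0.3, 0.3]])
        deltas = {}
        for tau in (6000.0, 15000.0):
            proj = make_proj(w0.copy(), tau_w=tau, w_max=1.2)
            update_shortcut(proj, pre, post, dt=1000.0)
            deltas[tau] = proj.W[0, 0] - 0.3
        assert deltas[6000.0] / deltas[15000.0] == pytest.approx(2.5)

    def test_fully_inhibited_thalamus_blocks_learning(self):
        """The basal ganglia veto: zero postsynaptic rate, zero change."""
        proj = make_proj(np.full((2, 6), 0.42), w_max=1.2)
        update_shortcut(proj, np.ones(6), np.zeros(2), dt=1000.0)
        np.testing.assert_array_equal(proj.W, 0.42)

    def test_non_plastic_shortcut_is_untouched_by_training(self):
        """With shortcut plasticity disabled the weights are bit-identical
        after a full training and test run."""
        result = run_subject(preset("no_shortcut_plasticity"), seed=11)
        np.testing.assert_array_equal(
            result.shortcut_W, np.full((2, 6), DEFAULT_PARAMS.shortcut_init))

    def test_invalid_tau_rejected(self):
        proj = make_proj(np.full((1, 1), 0.3), tau_w=None)
        proj.tau_w = -1.0
        with pytest.raises(ConfigurationError):
            update_shortcut(proj, np.ones(1), np.ones(1), 1000.0)

    def test_weights_clipped_to_bounds(self):
        proj = make_proj(np.full((1, 1), 0.3), w_max=0.5)
        for _ in range(200):
            update_shortcut(proj, np.ones(1), np.full(1, 2.0), dt=1000.0)
        assert proj.W[0, 0] == pytest.approx(0.5)


class TestLearningProperties:
    def test_flat_dopamine_leaves_corticostriatal_weights_at_init(self):
        """A training run with zero phasic amplitude does not move any
        dopamine-gated weight (the shortcut, being Hebbian, may still learn)."""
        config = replace(preset("control"), name="flat_da",
                         da_peak=0.5, da_tonic=0.5)
        task = build_task(9)
        init = {n: build_model(task, config, 9).net.projections[n].W.copy()
                for n, *_ in build_model(task, config, 9).corticostriatal}
        model = build_model(task, config, 9)
        from habitloops import _kernels
        from habitloops.task import block_order, encode_inputs, score_trial
        _kernels.seed_noise(9)
        rng = np.random.default_rng((9, 0xB10C))
        for block in range(10):
            for stim in block_order(task, rng):
                stim = int(stim)
                drive = encode_inputs(task, stim, "train", False)
                out = model.run_trial_selection(drive)
                _, rewarded = score_trial(task, stim, out.response, "train", False)
                model.run_learning_window(drive, rewarded, learn=True,
                                          responded=out.response != "NONE")
        for name, *_ in model.corticostriatal:
            np.testing.assert_array_equal(model.net.projections[name].W, init[name])

    def test_basal_ganglia_teacher_gates_shortcut_strength(self):
        """Doubling the pallido-thalamic inhibition suppresses the thalamic
        teacher and yields strictly smaller final shortcut weights."""
        strong = replace(DEFAULT_PARAMS,
                         w_mot_gpi_thal=2.0 * DEFAULT_PARAMS.w_mot_gpi_thal)
        control = run_subject(preset("control"), seed=21)
        gated = run_subject(preset("control"), seed=21, params=strong)
        assert gated.shortcut_mean < control.shortcut_mean

    def test_final_shortcut_weight_nonincreasing_in_tau(self, cohorts):
        """Matched seeds: the mean trained shortcut weight does not increase
        with the learning time constant across 6000..15000 ms."""
        order = ["fast_shortcut_6000", "shortcut_12000", "shortcut_14000",
                 "control"]
        means = np.array([cohorts.get(n).rates("shortcut_mean") for n in order])
        diffs = means[:-1] - means[1:]          # per-seed, faster minus slower
        assert (diffs >= -1e-9).all()
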