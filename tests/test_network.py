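"""Dynamics of the rate-unit network: integration accuracy, signs, stability."""

import numpy as np
import pytest

from habitloops import (DEFAULT_PARAMS, InstabilityError, Network, Projection,
                        RateUnitPopulation, apply_gain, build_model, build_task,
                        preset, read_response)
from habitloops import _kernels
from habitloops.model import step
from habitloops.network import ConfigurationError
from habitloops.task import InputDrive


def single_unit(tau=10.0, baseline=0.0, dt=1.0):
    net = Network(dt=dt)
    net.add(RateUnitPopulation("u", 1, tau_m=tau, baseline=baseline))
    net.finalize()
    return net


class TestEulerIntegration:
    def test_rest_fixed_point(self):
        """Zero input, zero baseline, zero noise: rates stay exactly zero."""
        net = single_unit()
        for _ in range(100):
            net.step()
        assert net.v[0] == 0.0 and net.r[0] == 0.0

    def test_matches_discrete_closed_form_at_coarse_step(self):
        """dt = 0.1 tau: the Euler trace equals the exact solution of the
        discrete map v_{n+1} = (1-k) v_n + k c to machine precision."""
        c, tau, dt = 0.7, 10.0, 1.0
        net = single_unit(tau=tau, dt=dt)
        k = dt / tau
        trace = []
        for _ in range(200):
            net.step(ext=np.array([c]))
            trace.append(net.v[0])
        n = np.arange(1, 201)
        expected = c * (1.0 - (1.0 - k) ** n)
        assert np.allclose(trace, expected, atol=1e-12)

    def test_converges_to_analytic_relaxation(self):
        """With a fine step the Euler trace tracks c (1 - exp(-t/tau)) within
        1e-3 everywhere, and the steady state matches exactly."""
        c, tau, dt = 1.0, 10.0, 0.05
        net = single_unit(tau=tau, dt=dt)
        ts, vs = [], []
        for i in range(int(50 * tau / dt)):
            net.step(ext=np.array([c]))
            ts.append((i + 1) * dt)
            vs.append(net.v[0])
        analytic = c * (1 - np.exp(-np.asarray(ts) / tau))
        assert np.max(np.abs(np.asarray(vs) - analytic)) < 1e-3
        assert abs(vs[-1] - c) < 1e-6

    def test_kernel_matches_reference_step(self):
        """The compiled integrator and the numpy reference produce identical
        noise-free trajectories on a full model."""
        task = build_task(3)
        m1 = build_model(task, preset("control"), 3)
        m2 = build_model(task, preset("control"), 3)
        for m in (m1, m2):
            m.net.noise_vec[:] = 0.0
        ext = m1._ext_vector(InputDrive(stim=np.eye(6)[0], goal=np.eye(6)[2]))
        m1.net.reset()
        m2.net.reset()
        _kernels.run_phase(m1.net.G, m1.net.v, m1.net.r, m1.net.tau,
                           m1.net.baseline, m1.net.gain_vec, ext, 1.0, 50,
                           m1.net.noise_vec, 0, 0, 0.0, np.zeros(0), False,
                           1e9, 0.0)
        for _ in range(50):
            m2.net.step(ext=ext)
        np.testing.assert_allclose(m1.net.r, m2.net.r, atol=1e-10)


class TestSignsAndGates:
    def test_inhibitory_projection_suppresses_target(self):
        net = Network()
        src = net.add(RateUnitPopulation("src", 1, baseline=1.0))
        tgt = net.add(RateUnitPopulation("tgt", 1, baseline=0.8))
        net.connect(Projection("inh", src, tgt, np.array([[0.5]]), sign=-1))
        net.finalize()
        for _ in range(200):
            net.step()
        assert net.r[tgt.sl][0] == pytest.approx(0.8 - 0.5 * 1.0, abs=1e-6)

    def test_pallidal_disinhibition_is_monotonic(self):
        """Scaling GPi->thalamus down strictly increases the steady-state
        thalamic rate under fixed drive (three scale probes)."""
        rates = []
        for scale in (1.0, 0.6, 0.2):
            net = Network()
            gpi = net.add(RateUnitPopulation("gpi", 1, baseline=1.0))
            thal = net.add(RateUnitPopulation("thal", 1, baseline=0.8))
            net.connect(Projection("gpi_thal", gpi, thal,
                                   np.array([[0.5 * scale]]), sign=-1))
            net.finalize()
            for _ in range(300):
                net.step()
            rates.append(net.r[thal.sl][0])
        assert rates[0] < rates[1] < rates[2]

    def test_gpi_baseline_holds_thalamus_below_uninhibited_level(self,
                                                                 control_model):
        """With tonic GPi and no striatal activity the motor thalamus sits
        below its uninhibited drive."""
        m = control_model
        m.net.noise_vec[:] = 0.0
        m.net.reset()
        for _ in range(300):
            m.net.step()
        p = DEFAULT_PARAMS
        assert m.rates("mot_gpi").min() > 0.5
        assert m.rates("mot_thal").max() < p.mot_thal_base

    def test_rest_state_is_stable(self, control_model):
        """Without stimulus or goal drive no rate exceeds the baseline-driven
        bound over a long simulation."""
        m = control_model
        m.net.reset()
        zeros = np.zeros(m.net.n_units)
        status, steps, unit, _ = m._phase(zeros, 10_000)
        assert status == _kernels.DONE
        assert m.net.r.max() < 2.0


class TestTransferAndResponse:
    def test_gain_examples(self):
        assert apply_gain(-0.5, 1.02) == 0.0
        assert apply_gain(1.0, 1.0) == 1.0
        assert apply_gain(1.0, 1.02, "d1") == pytest.approx(1.02)
        assert apply_gain(1.0, 1.02, "d2") == pytest.approx(1.0 / 1.02)
        with pytest.raises(ConfigurationError):
            apply_gain(1.0, 0.0)

    @pytest.mark.parametrize("rates,expected", [
        ([1.2, 0.1], 0), ([0.1, 1.2], 1),
        ([1.2, 1.3], 1),             # both cross: higher rate wins
        ([1.2, 1.2], 0),             # exact tie: lower index wins
    ])
    def test_threshold_crossing_winner(self, rates, expected):
        """First-crossing readout: highest rate above threshold, ties to the
        lower index."""
        net = Network()
        pop = net.add(RateUnitPopulation("out", 2, tau_m=1.0))
        net.finalize()
        ext = np.asarray(rates, dtype=float)
        status, steps, unit = _kernels.run_phase(
            net.G, net.v, net.r, net.tau, net.baseline, net.gain_vec, ext,
            1.0, 500, net.noise_vec, 0, 2, 1.0, np.zeros(0), False, 1e9, 0.0)
        assert status == _kernels.CROSSED
        assert unit == expected

    def test_timeout_returns_none(self, control_model):
        m = control_model
        out = m.run_trial_selection(InputDrive(stim=np.zeros(6), goal=np.zeros(6)))
        assert out.response == "NONE"
        assert read_response(m) == "NONE"

    def test_step_op_raises_on_runaway(self, control_model):
        m = control_model
        m.net.projections["mot_thal_ctx"].W[:] = 1e6
        m.net.refresh(m.net.projections["mot_thal_ctx"])
        m.net.reset()
        m.net.v[m.net.populations["mot_thal"].sl] = 10.0
        drive = InputDrive(stim=np.ones(6), goal=np.ones(6))
        with pytest.raises(InstabilityError) as exc:
            for _ in range(50):
                step(m, drive, dt=1.0)
        assert exc.value.population  # carries the population name


class TestDeterminism:
    def test_identical_seeds_give_identical_traces(self):
        task = build_task(5)
        traces = []
        for _ in range(2):
            m = build_model(task, preset("control"), 5)
            _kernels.seed_noise(5)
            drive = InputDrive(stim=np.eye(6)[1], goal=np.eye(6)[3])
            out = m.run_trial_selection(drive)
            traces.append((out.response, out.rt_ms, m.net.r.copy()))
        assert traces[0][0] == traces[1][0]
        assert traces[0][1] == traces[1][1]
        np.testing.assert_array_equal(traces[0][2], traces[1][2])

    def test_identical_seeds_give_identical_initial_weights(self):
        task = build_task(7)
        w1 = build_model(task, preset("control"), 7).shortcut.W
        w2 = build_model(task, preset("control"), 7).shortcut.W
        np.testing.assert_array_equal(w1, w2)
        cl1 = build_model(task, preset("control"), 7).crosslink.W
        cl2 = build_model(task, preset("control"), 7).crosslink.W
        np.testing.assert_array_equal(cl1, cl2)
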