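"""Synthetic-data generator: determinism, construction guarantees and
law-of-large-numbers convergence to configured truths."""

import numpy as np
import pytest

from epicortex import core, synth
from epicortex.classify import halfmax_width
from epicortex.firing import burstiness_index


class TestMakeUnits:
    def test_zero_units(self):
        cfg = synth.SimConfig(n_rs=0, n_ib=0, n_in=0, n_uc=0)
        us, gt = synth.make_units(cfg, np.random.default_rng(0))
        assert len(us) == 0 and gt.unit_class == {}

    def test_interneuron_templates_are_narrow(self):
        cfg = synth.SimConfig(n_rs=0, n_ib=0, n_in=5, n_uc=0)
        us, gt = synth.make_units(cfg, np.random.default_rng(3))
        for u in us.units:
            assert halfmax_width(u.mean_waveform, u.waveform_fs) < 0.2

    def test_class_width_margins(self, sim_config):
        us, gt = synth.make_units(sim_config, np.random.default_rng(1))
        for u in us.units:
            w = halfmax_width(u.mean_waveform, u.waveform_fs)
            cls = gt.unit_class[u.unit_id]
            if cls in ("RS-PC", "IB-PC"):
                assert w > 0.45
            elif cls == "IN":
                assert w < 0.18
            else:
                assert 0.2 < w < 0.4

    def test_fixed_seed_is_deterministic(self, sim_config):
        a, _ = synth.make_units(sim_config, np.random.default_rng(9))
        b, _ = synth.make_units(sim_config, np.random.default_rng(9))
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.mean_waveform, ub.mean_waveform)
            assert ua.channel == ub.channel


class TestSimulateTrains:
    def test_zero_rate_gives_empty_train(self, sim_config, control_epoch):
        gt = synth.GroundTruth({"u": "RS-PC"}, {"u": {"control": 0.0}},
                               {"u": None}, {"u": 1.0}, [])
        us = synth.simulate_trains(gt, control_epoch, sim_config,
                                   np.random.default_rng(0))
        assert us["u"].n_spikes == 0

    def test_poisson_count_convergence(self, sim_config, control_epoch):
        """Mean spike count over replicates matches the Poisson truth."""
        gt = synth.GroundTruth({"u": "RS-PC"}, {"u": {"control": 2.0}},
                               {"u": None}, {"u": 1.0}, [])
        counts = []
        for s in range(200):
            us = synth.simulate_trains(gt, control_epoch, sim_config,
                                       np.random.default_rng(500 + s))
            counts.append(us["u"].n_spikes)
        mean = np.mean(counts)
        # SE of the replicate mean of a Poisson(600) count
        assert abs(mean - 600.0) < 3 * np.sqrt(600.0 / 200)

    def test_full_burst_fraction_gives_burstiness_one(self, control_epoch):
        cfg = synth.SimConfig(burst_fraction=1.0, burst_size_band=(3, 3))
        gt = synth.GroundTruth(
            {"u": "IB-PC"}, {"u": {"control": 2.0}},
            {"u": {"fraction": 1.0, "size_band": (3, 3),
                   "intra_isi_ms": (3.0, 5.0)}},
            {"u": 1.0}, [])
        us = synth.simulate_trains(gt, control_epoch, cfg,
                                   np.random.default_rng(4))
        assert burstiness_index(us["u"].spike_times) == 1.0

    def test_spikes_stay_inside_epochs(self, synthetic_recording, control_epoch):
        trains, _ = synthetic_recording
        (epoch,) = control_epoch.epochs
        for u in trains.units:
            if u.n_spikes:
                assert u.spike_times[0] >= epoch.start
                assert u.spike_times[-1] <= epoch.end


class TestInjectConnection:
    def test_certain_transmission_no_jitter(self):
        rng = np.random.default_rng(0)
        pre = np.sort(rng.uniform(0, 100, 200))
        post = synth.inject_connection(pre, np.empty(0), 2.0, 1.0, 0.0, rng)
        # every pre spike has a post spike exactly +2 ms later
        assert post.size == pre.size
        np.testing.assert_allclose(post - np.sort(pre + 0.002), 0, atol=1e-9)

    def test_zero_probability_identity(self):
        rng = np.random.default_rng(0)
        pre = np.sort(rng.uniform(0, 100, 200))
        post = np.sort(rng.uniform(0, 100, 150))
        out = synth.inject_connection(pre, post, 2.0, 0.0, 0.5, rng)
        np.testing.assert_array_equal(out, post)

    def test_added_count_is_binomial(self):
        rng = np.random.default_rng(7)
        pre = np.sort(rng.uniform(0, 600, rng.poisson(5 * 600)))
        post = np.sort(rng.uniform(0, 600, rng.poisson(1 * 600)))
        out = synth.inject_connection(pre, post, 2.0, 0.3, 0.3, rng)
        added = out.size - post.size
        n, p = pre.size, 0.3
        assert abs(added - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(ValueError):
            synth.inject_connection(np.array([1.0]), np.empty(0), 0.0, 0.5,
                                    0.1, np.random.default_rng(0))


class TestSimulateSPA:
    def test_poisson_limit_event_count(self):
        """Gamma shape 1 is a Poisson process: count within 3 sigma."""
        cfg = synth.SimConfig(spa_rate_hz=1.0, spa_gamma_shape=1.0)
        counts = [synth.simulate_spa(cfg, 300.0, np.random.default_rng(s),
                                     with_traces=False).n_events
                  for s in range(100)]
        assert abs(np.mean(counts) - 300.0) < 3 * np.sqrt(300.0 / 100) + 1
        # single-realization spread obeys the renewal band too
        assert all(abs(c - 300) < 3 * np.sqrt(300) + 2 for c in counts)

    def test_noise_free_trace_amplitude_is_exact(self):
        cfg = synth.SimConfig(lfpg_amplitude_uv=22.0, mua_amplitude_uv=1.4,
                              lfpg_noise_uv=0.0, mua_noise_uv=0.0)
        ev = synth.simulate_spa(cfg, 120.0, np.random.default_rng(0))
        from epicortex.spa import event_triggered_average, spa_amplitudes
        lf = event_triggered_average(ev.lfpg_traces, ev.trace_time_ms)
        mu = event_triggered_average(ev.mua_traces, ev.trace_time_ms)
        a_lf, a_mu = spa_amplitudes(lf, mu, ev.trace_time_ms)
        assert a_lf == pytest.approx(22.0, rel=1e-3)
        assert a_mu == pytest.approx(1.4, rel=1e-3)

    def test_rate_must_be_positive(self):
        cfg = synth.SimConfig(spa_rate_hz=0.0)
        with pytest.raises(ValueError):
            synth.simulate_spa(cfg, 100.0, np.random.default_rng(0))


class TestRenderCellsImage:
    def test_zero_cells_background_only(self, sim_config):
        img, cents = synth.render_cells_image(0, sim_config,
                                              np.random.default_rng(0))
        assert cents.shape == (0, 2)
        assert img.min() > 100  # nothing as dark as a soma

    def test_exact_component_count_without_noise(self, sim_config):
        from scipy.ndimage import label
        img, cents = synth.render_cells_image(
            50, sim_config, np.random.default_rng(1), noise_sigma=0.0)
        comp, n = label(img < 128)
        assert n == 50 and cents.shape == (50, 2)

    def test_fixed_seed_byte_identical(self, sim_config):
        a, _ = synth.render_cells_image(20, sim_config, np.random.default_rng(5))
        b, _ = synth.render_cells_image(20, sim_config, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_overcrowding_rejected(self):
        cfg = synth.SimConfig(image_shape=(64, 64), min_separation_px=24.0)
        with pytest.raises(ValueError):
            synth.render_cells_image(50, cfg, np.random.default_rng(0))


class TestSimulateSynapseTable:
    def test_zero_perforation_probability(self):
        cfg = synth.SimConfig(perforation_p={"non-epileptic": 0.0,
                                             "epileptic": 0.0})
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(0))
        assert not df["perforated"].any()

    def test_spine_fraction_converges(self):
        cfg = synth.SimConfig(
            synapse_n={"non-epileptic": 10_000, "epileptic": 10},
            target_p={"non-epileptic": (0.665, 0.302, 0.033),
                      "epileptic": (0.665, 0.302, 0.033)})
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(2))
        syn = df[df.group == "non-epileptic"].drop_duplicates("synapse_id")
        f = (syn.target == "spine").mean()
        assert abs(f - 0.665) < 3 * np.sqrt(0.665 * 0.335 / 10_000)

    def test_zone_level_perforation_matches_printed_convention(self):
        """Configured probabilities are the active-zone ratios."""
        cfg = synth.SimConfig(
            synapse_n={"non-epileptic": 20_000, "epileptic": 10})
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(3))
        g = df[df.group == "non-epileptic"]
        assert g["perforated"].mean() == pytest.approx(0.204, abs=0.015)

    def test_perforated_invariant_holds(self):
        cfg = synth.SimConfig()
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(4))
        from epicortex.synapse import validate_records
        validate_records(df)
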