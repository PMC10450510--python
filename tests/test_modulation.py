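"""Peri-event window counting, modulation classes and Granger screening."""

import numpy as np
import pytest

from epicortex import synth
from epicortex.core import Epoch, EpochSet, SPAEventSet
from epicortex.modulation import (granger_unit_to_spa, modulation_class,
                                  window_counts)


class TestWindowCounts:
    events = SPAEventSet(np.array([10.0, 20.0, 30.0]))

    def test_no_spikes_all_zero(self):
        out = window_counts(np.empty(0), self.events, 100.0)
        np.testing.assert_array_equal(out, 0)

    def test_baseline_window_membership(self):
        out = window_counts(np.array([9.9]), self.events, 100.0)  # event-100 ms
        np.testing.assert_array_equal(out[0], [1, 0])

    def test_spike_at_time_zero_counts_as_peri(self):
        out = window_counts(np.array([10.0]), self.events, 100.0)
        np.testing.assert_array_equal(out[0], [0, 1])

    def test_clipped_events_dropped(self):
        ev = SPAEventSet(np.array([0.05, 10.0]))  # first event's baseline < 0
        out = window_counts(np.array([9.9]), ev, 100.0)
        assert out.shape == (1, 2)

    def test_windows_tile_without_overlap(self):
        # every spike in [-150, +50) ms lands in exactly one window
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(9.8, 10.1, 200))
        out = window_counts(t, SPAEventSet(np.array([10.0])), 100.0)
        in_range = np.count_nonzero((t >= 10.0 - 0.150) & (t < 10.0 + 0.050))
        assert out.sum() == in_range


class TestModulationClass:
    def test_identical_counts_unchanged(self):
        pairs = np.tile([3, 3], (50, 1))
        assert modulation_class(pairs).label == "unchanged"

    def test_small_significant_change_gated_to_unchanged(self):
        # consistently higher peri counts but only +33%: the 50% gate holds
        rng = np.random.default_rng(0)
        base = rng.poisson(30, 200)
        pairs = np.column_stack([base, base + rng.poisson(10, 200)])
        res = modulation_class(pairs)
        assert res.p < 0.05 and res.label == "unchanged"

    def test_too_few_events_flagged(self):
        res = modulation_class(np.tile([0, 5], (5, 1)))
        assert res.label == "unchanged" and "insufficient" in res.flags

    def test_silent_baseline_reports_infinite_change(self):
        pairs = np.column_stack([np.zeros(50, int),
                                 np.random.default_rng(0).poisson(3, 50)])
        res = modulation_class(pairs)
        assert np.isinf(res.change_pct) and res.label == "increased"

    def test_simulated_threefold_modulation_detected(self, sim_config):
        hits = 0
        n = 100
        epochs = EpochSet([Epoch("control", 0, 300)])
        for s in range(n):
            rng = np.random.default_rng(2000 + s)
            ev = synth.simulate_spa(sim_config, 300.0, rng, with_traces=False)
            gt = synth.GroundTruth({"u": "RS-PC"}, {"u": {"control": 2.0}},
                                   {"u": None}, {"u": 3.0}, [])
            tr = synth.simulate_trains(gt, epochs, sim_config, rng,
                                       spa_events=ev)
            counts = window_counts(tr["u"].spike_times, ev, 300.0)
            hits += modulation_class(counts).label == "increased"
        assert hits >= 95

    def test_null_calibration_with_gate(self):
        """No modulation: increased+decreased calls stay at/below alpha."""
        calls = 0
        n = 200
        epochs = EpochSet([Epoch("control", 0, 300)])
        cfg = synth.SimConfig(seed=0)
        for s in range(n):
            rng = np.random.default_rng(40_000 + s)
            ev = synth.simulate_spa(cfg, 300.0, rng, with_traces=False)
            gt = synth.GroundTruth({"u": "RS-PC"}, {"u": {"control": 2.0}},
                                   {"u": None}, {"u": 1.0}, [])
            tr = synth.simulate_trains(gt, epochs, cfg, rng, spa_events=ev)
            counts = window_counts(tr["u"].spike_times, ev, 300.0)
            calls += modulation_class(counts).label != "unchanged"
        assert calls / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)


class TestGranger:
    def test_planted_causality_detected(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(4000 + s)
            sp = np.sort(rng.uniform(0, 300, rng.poisson(2 * 300)))
            ev_t = np.sort(sp + 0.030)
            ev = SPAEventSet(ev_t[(ev_t > 0.2) & (ev_t < 299.8)])
            g = granger_unit_to_spa(sp, ev, 300.0)
            hits += g.p < 0.01
        assert hits >= 29

    def test_shuffled_unit_fails(self):
        rng = np.random.default_rng(5)
        sp = np.sort(rng.uniform(0, 300, rng.poisson(2 * 300)))
        ev_t = np.sort(sp + 0.030)
        ev = SPAEventSet(ev_t[(ev_t > 0.2) & (ev_t < 299.8)])
        shuffled = np.sort(rng.uniform(0, 300, sp.size))  # timing destroyed
        g = granger_unit_to_spa(shuffled, ev, 300.0)
        assert not g.passes

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            granger_unit_to_spa(np.array([1.0]), SPAEventSet(np.array([2.0])),
                                30.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            granger_unit_to_spa(np.empty(0), SPAEventSet(np.array([2.0])),
                                100.0)

    def test_f_statistic_matches_statsmodels(self):
        """Same F and p as the reference ssr-based Granger test at fixed order."""
        from statsmodels.tsa.stattools import grangercausalitytests
        rng = np.random.default_rng(6)
        sp = np.sort(rng.uniform(0, 300, rng.poisson(2 * 300)))
        ev = SPAEventSet(np.sort(rng.uniform(0.2, 299.8, 280)))
        order = 5
        mine = granger_unit_to_spa(sp, ev, 300.0, order=order)

        from epicortex.modulation import _bin_counts
        y = _bin_counts(ev.event_times, 300.0, 0.010)
        x = _bin_counts(sp, 300.0, 0.010)
        res = grangercausalitytests(np.column_stack([y, x]), maxlag=[order])
        f_ref, p_ref, *_ = res[order][0]["ssr_ftest"]
        assert mine.f_statistic == pytest.approx(f_ref, rel=1e-6)
        assert mine.p == pytest.approx(p_ref, rel=1e-6)
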