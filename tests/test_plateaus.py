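"""Plateau detection, duration statistics, shape metrics, and regime
classification."""

import numpy as np
import pytest

from pharynxsim import ModelParameters, simulate_reference_protocol
from pharynxsim.integrator import reference_schedule
from pharynxsim.plateaus import (PlateauSegment, Regime, classify_regime,
                                 detect_plateaus, duration_stats,
                                 mark_commanded, mean_plateau_duration,
                                 plateau_levels, wedge_depth)
from conftest import make_trace


class TestDetector:
    def test_square_pulse(self, square_trace_factory):
        tr = square_trace_factory(levels=((100.0, 350.0, 40.0),))
        segs = detect_plateaus(tr, threshold=-30.0, min_duration=5.0)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.duration == pytest.approx(250.0, abs=0.5)
        assert seg.V_peak == 40.0
        assert not seg.open_ended

    def test_constant_trace_is_empty(self, square_trace_factory):
        tr = square_trace_factory(levels=())
        assert detect_plateaus(tr) == []

    def test_min_duration_filters_short_pulse(self, square_trace_factory):
        tr = square_trace_factory(levels=((100.0, 150.0, 40.0),
                                          (300.0, 303.0, 40.0)))
        segs = detect_plateaus(tr, min_duration=5.0)
        assert len(segs) == 1
        assert segs[0].t_on < 150.0

    def test_open_ended_flagged(self, square_trace_factory):
        tr = square_trace_factory(t_total=500.0,
                                  levels=((100.0, 600.0, 40.0),))
        segs = detect_plateaus(tr)
        assert len(segs) == 1 and segs[0].open_ended

    def test_interpolated_crossings_refine_grid(self):
        # linear ramp crossing -30 exactly halfway between samples
        times = np.arange(0.0, 40.5, 0.5)
        V = np.where(times < 10, -65.0,
                     np.where(times < 30, 40.0, -65.0))
        V[times == 10] = -65 + (40 + 65) * 0.5
        tr = make_trace(times, V)
        seg = detect_plateaus(tr)[0]
        assert 9.5 < seg.t_on < 10.5

    def test_refinement_invariance_on_model_trace(self, params):
        d = {}
        for dt in (0.5, 0.25):
            tr = simulate_reference_protocol(params, None, t_total=1100.0,
                                             dt_out=dt)
            d[dt] = [s.duration for s in detect_plateaus(tr)]
        assert len(d[0.5]) == len(d[0.25])
        assert np.abs(np.array(d[0.5]) - np.array(d[0.25])).max() < 1.0


def _segments(durations):
    return [PlateauSegment(t_on=0.0, t_off=float(d), V_peak=40.0)
            for d in durations]


def test_mean_duration():
    assert mean_plateau_duration(_segments([250.0, 250.0])) == 250.0
    assert mean_plateau_duration(_segments([100.0, 300.0])) == 200.0
    mean, n, empty = duration_stats([])
    assert (mean, n, empty) == (0.0, 0, True)
    # open-ended segments are excluded
    segs = _segments([250.0]) + [PlateauSegment(0.0, 400.0, 40.0,
                                                open_ended=True)]
    assert mean_plateau_duration(segs) == 250.0


def test_commanded_termination_window(params):
    sched = reference_schedule(params, None, 1100.0)
    segs = mark_commanded(_segments([255.0]), sched, window_ms=25.0)
    # t_off = 255 is not within 25 ms after any IPSP (350, 850)
    assert segs[0].terminated_by_command is False
    seg = PlateauSegment(t_on=101.0, t_off=352.0, V_peak=40.0)
    assert mark_commanded([seg], sched)[0].terminated_by_command is True


class TestWedge:
    def test_constructed_dip(self):
        times = np.arange(0.0, 300.0, 0.5)
        V = np.full(times.size, -65.0)
        sel = (times >= 50) & (times < 250)
        tt = times[sel] - 50
        prof = np.where(tt < 10, 40.0, np.where(tt < 40, 25.0, 38.0))
        V[sel] = prof
        tr = make_trace(times, V)
        seg = detect_plateaus(tr)[0]
        assert wedge_depth(tr, seg) == pytest.approx(15.0, abs=0.5)

    def test_monotone_relaxation_has_no_wedge(self, noiseless_trace):
        seg = detect_plateaus(noiseless_trace)[0]
        assert wedge_depth(noiseless_trace, seg) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_early_minimum_deepens_with_inactivation_timescale(self, params):
        """The hyperpolarizing wedge after plateau onset deepens
        monotonically as K inactivation slows."""
        early_min = []
        for th in (1.0, 5.0, 10.0, 20.0):
            tr = simulate_reference_protocol(params.replace(tau_h=th), None,
                                             t_total=700.0)
            seg = detect_plateaus(tr)[0]
            sel = (tr.times >= seg.t_on) & (tr.times <= seg.t_on + 100.0)
            early_min.append(tr.V[sel].min())
        assert all(a > b for a, b in zip(early_min, early_min[1:]))


class TestRegimes:
    def test_two_level_constructed(self, params):
        times = np.arange(0.0, 1100.5, 0.5)
        V = np.full(times.size, -65.0)
        V[(times >= 100) & (times < 400)] = 40.0
        V[(times >= 400) & (times < 700)] = 0.0
        tr = make_trace(times, V)
        sched = reference_schedule(params, None, 1100.0)
        assert classify_regime(tr, sched) is Regime.TWO_LEVEL
        seg = detect_plateaus(tr)[0]
        upper, lower = plateau_levels(tr, seg)
        assert upper == pytest.approx(40.0, abs=1.0)
        assert lower == pytest.approx(0.0, abs=1.0)

    def test_single_level_has_no_bands(self, noiseless_trace):
        seg = detect_plateaus(noiseless_trace)[0]
        assert plateau_levels(noiseless_trace, seg) is None

    def test_unending(self, params):
        times = np.arange(0.0, 2100.5, 0.5)
        V = np.where(times < 100, -65.0, 40.0)
        tr = make_trace(times, V)
        sched = reference_schedule(params, None, 2100.0)
        assert classify_regime(tr, sched) is Regime.UNENDING

    def test_noiseless_reference_is_physiological(self, noiseless_trace,
                                                  noiseless_schedule):
        assert classify_regime(noiseless_trace,
                               noiseless_schedule) is Regime.PHYSIOLOGICAL

    def test_quiescent_flat_trace(self, square_trace_factory, params):
        tr = square_trace_factory(levels=())
        sched = reference_schedule(params, None, 1100.0)
        assert classify_regime(tr, sched) is Regime.QUIESCENT

    def test_low_amplitude(self, square_trace_factory, params):
        tr = square_trace_factory(levels=((100.0, 200.0, -40.0),
                                          (600.0, 700.0, -40.0)))
        sched = reference_schedule(params, None, 1100.0)
        assert classify_regime(tr, sched) is Regime.LOW_AMPLITUDE
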