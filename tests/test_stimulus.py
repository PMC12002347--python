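"""Feeding-command schedules, Poisson shot-noise trains, and event
application semantics."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from pharynxsim import ModelParameters, StateVector
from pharynxsim.stimulus import (EPSP, IPSP, NOISE, EventSchedule,
                                 NoiseConfig, SynapticEvent, apply_event,
                                 build_feeding_schedule, merge_schedules,
                                 sample_noise_train)


class TestFeedingSchedule:
    def test_reference_timing(self):
        s = build_feeding_schedule(250.0, 250.0, 1100.0, 100.0)
        epsp = [ev.t for ev in s.events if ev.kind == EPSP]
        ipsp = [ev.t for ev in s.events if ev.kind == IPSP]
        assert epsp == [100.0, 600.0]
        assert ipsp == [350.0, 850.0]
        assert all(ev.magnitude == 3.0 for ev in s.events
                   if ev.kind == EPSP)
        assert all(ev.magnitude == 2.5 for ev in s.events
                   if ev.kind == IPSP)

    def test_first_plateau_must_fit(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_feeding_schedule(250.0, 250.0, 200.0, 100.0)

    def test_pair_count_by_enumeration(self):
        s = build_feeding_schedule(10.0, 10.0, 100.0, 0.0)
        assert sum(ev.kind == EPSP for ev in s.events) == 5
        assert sum(ev.kind == IPSP for ev in s.events) == 5

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            build_feeding_schedule(-1.0, 250.0, 1000.0, 100.0)
        with pytest.raises(ValueError):
            build_feeding_schedule(250.0, 0.0, 1000.0, 100.0)


class TestApplyEvent:
    def test_noise_adds_to_gI(self):
        st = StateVector(gI=0.4)
        out = apply_event(st, SynapticEvent(0.0, NOISE, 0.30))
        assert out.gI == pytest.approx(0.70)
        assert out.gE == st.gE

    def test_epsp_assigns_not_adds(self):
        out = apply_event(StateVector(gE=0.2), SynapticEvent(0.0, EPSP, 3.0))
        assert out.gE == 3.0

    def test_ipsp_assignment_idempotent(self):
        out = apply_event(StateVector(gI=2.5), SynapticEvent(0.0, IPSP, 2.5))
        assert out.gI == 2.5

    def test_only_target_conductance_changes(self):
        st = StateVector(V=1.0, w=0.5, gE=0.7, gI=0.2)
        out = apply_event(st, SynapticEvent(0.0, NOISE, 0.15))
        assert (out.V, out.w, out.gE) == (st.V, st.w, st.gE)


class TestNoiseTrain:
    def test_zero_rate_is_empty(self):
        assert len(sample_noise_train(NoiseConfig(lam=0.0, seed=1),
                                      1000.0)) == 0

    def test_determinism_and_seed_sensitivity(self):
        cfg = NoiseConfig(lam=0.05, bin_ms=1.0, seed=11)
        a = sample_noise_train(cfg, 5000.0)
        b = sample_noise_train(cfg, 5000.0)
        assert a.events == b.events
        c = sample_noise_train(NoiseConfig(lam=0.05, bin_ms=1.0, seed=12),
                               5000.0)
        assert a.events != c.events

    def test_all_events_are_inhibitory_noise_quanta(self):
        train = sample_noise_train(NoiseConfig(lam=0.05, bin_ms=1.0, seed=3),
                                   10_000.0, noise_quantum=0.15)
        assert all(ev.kind == NOISE for ev in train.events)
        for ev in train.events:
            k = ev.magnitude / 0.15
            assert k == pytest.approx(round(k)) and k >= 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_total_count_near_poisson_mean(self, seed):
        # lam=0.05/bin over 20,000 bins: total ~ Poisson(1000)
        train = sample_noise_train(
            NoiseConfig(lam=0.05, bin_ms=1.0, seed=seed), 20_000.0)
        total = round(sum(ev.magnitude for ev in train.events) / 0.15)
        assert abs(total - 1000) < 3 * np.sqrt(1000)

    def test_mean_gap_matches_rate(self):
        # lam=0.01/bin at 1 ms bins: mean gap between nonzero bins ~ 100 ms
        train = sample_noise_train(
            NoiseConfig(lam=0.01, bin_ms=1.0, seed=5), 2_000_000.0)
        gaps = np.diff([ev.t for ev in train.events])
        assert gaps.mean() == pytest.approx(100.0, rel=0.05)

    def test_per_bin_histogram_matches_poisson_pmf(self):
        lam, n_bins = 0.8, 100_000
        counts = np.random.default_rng(123).poisson  # independent oracle draw
        cfg = NoiseConfig(lam=lam, bin_ms=1.0, seed=123)
        train = sample_noise_train(cfg, float(n_bins))
        ks = np.zeros(n_bins, dtype=int)
        for ev in train.events:
            ks[int(ev.t)] = round(ev.magnitude / 0.15)
        kmax = 6
        observed = np.bincount(np.minimum(ks, kmax), minlength=kmax + 1)
        pmf = sps.poisson.pmf(np.arange(kmax), lam)
        expected = np.append(pmf, 1.0 - pmf.sum()) * n_bins
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, df=kmax)
        assert p > 0.01


class TestScheduleContainer:
    def test_merge_applies_tie_order(self):
        a = EventSchedule((SynapticEvent(100.0, IPSP, 2.5),), 1000.0)
        b = EventSchedule((SynapticEvent(100.0, EPSP, 3.0),
                           SynapticEvent(100.0, NOISE, 0.15)), 1000.0)
        m = merge_schedules(a, b)
        assert [ev.kind for ev in m.events] == [EPSP, IPSP, NOISE]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            EventSchedule((SynapticEvent(5.0, EPSP, 3.0),
                           SynapticEvent(1.0, EPSP, 3.0)), 10.0)
        with pytest.raises(ValueError, match="t_total"):
            EventSchedule((SynapticEvent(10.0, EPSP, 3.0),), 10.0)
        with pytest.raises(ValueError, match="kind"):
            SynapticEvent(0.0, "SPIKE", 1.0)
        with pytest.raises(ValueError):
            SynapticEvent(-1.0, EPSP, 1.0)

    def test_csv_round_trip_bit_exact(self):
        cmd = build_feeding_schedule(250.0, 250.0, 2000.0, 100.0)
        noise = sample_noise_train(NoiseConfig(lam=0.05, seed=9), 2000.0)
        sched = merge_schedules(cmd, noise)
        buf = io.StringIO()
        sched.to_csv(buf)
        buf.seek(0)
        back = EventSchedule.from_csv(buf)
        assert back == sched
        assert back.digest() == sched.digest()
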