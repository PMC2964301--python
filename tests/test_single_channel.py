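"""Resolvable openings, amplitude mixtures, conductances, bursts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pentafit as pf
from pentafit.single_channel import Event, rise_time
from pentafit.synthetic import (
    HIGH_CONDUCTANCE_CLASS,
    LOW_CONDUCTANCE_CLASS,
    ChannelClassSpec,
    simulate_single_channel,
)
from dataclasses import replace


def record_from(durations_and_amps, holding=-100.0, cutoff=1.0, resolution=50.0):
    """Build an alternating record from (open_ms, amp, shut_ms) triples."""
    events = []
    for i, (op, amp, sh) in enumerate(durations_and_amps):
        events.append(Event("open", op, amp))
        if sh is not None:
            events.append(Event("shut", sh))
    return pf.IdealizedRecord(events, holding, cutoff, resolution)


class TestFilterResolvable:
    def test_rise_time_rule_at_one_khz(self):
        assert rise_time(1.0) == pytest.approx(0.3321, rel=1e-12)
        rec = record_from([(0.5, 2.6, 10.0), (0.7, 3.9, None)])
        amps, durs = pf.filter_resolvable(rec)
        # 0.5 ms < 2*0.3321 excluded; 0.7 ms > 0.6642 retained
        assert list(amps) == [3.9]

    def test_all_long_openings_retained(self):
        rec = record_from([(5.0, 2.0, 3.0), (6.0, 2.5, 3.0), (7.0, 3.0, None)])
        amps, _ = pf.filter_resolvable(rec)
        assert amps.size == 3

    def test_zero_cutoff_rejected(self):
        with pytest.raises(pf.DomainError):
            rise_time(0.0)

    def test_nothing_survives_warns(self):
        rec = record_from([(0.1, 2.0, None)])
        with pytest.warns(UserWarning):
            amps, _ = pf.filter_resolvable(rec)
        assert amps.size == 0


class TestAmplitudeMixture:
    def test_single_class_recovery(self):
        rng = np.random.default_rng(5)
        amps = rng.normal(2.7, 0.3, 300)
        mix = pf.fit_amplitude_mixture(amps, k=1)
        mean, sd, area = mix.components[0]
        se = 0.3 / math.sqrt(300)
        assert mean == pytest.approx(2.7, abs=3 * se)
        assert area == 1.0

    def test_two_class_recovery(self):
        rng = np.random.default_rng(6)
        n = 500
        n1 = int(round(0.27 * n))
        amps = np.concatenate(
            [rng.normal(2.6, 0.5, n1), rng.normal(3.9, 0.4, n - n1)]
        )
        mix = pf.fit_amplitude_mixture(amps, k=2)
        (m1, s1, a1), (m2, s2, a2) = mix.components
        assert m1 < m2
        assert a1 == pytest.approx(0.27, abs=0.08)
        assert a2 == pytest.approx(0.73, abs=0.08)

    def test_floor_enforced(self):
        with pytest.raises(pf.InsufficientDataError):
            pf.fit_amplitude_mixture(np.ones(50) * 2.0)

    def test_auto_selects_one_component_on_single_gaussian(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            amps = rng.normal(2.7, 0.3, 300)
            mix = pf.fit_amplitude_mixture(amps, k="auto")
            hits += len(mix.components) == 1
        assert hits / n_rep >= 0.90


class TestChordConductance:
    @pytest.mark.parametrize("amp,expected", [(2.6, 26.0), (3.9, 39.0), (0.0, 0.0)])
    def test_paper_values_at_minus_100mv(self, amp, expected):
        assert pf.chord_conductance(amp, -100.0, 0.0) == pytest.approx(expected, rel=1e-9)

    def test_sign_invariance_and_linearity(self):
        assert pf.chord_conductance(2.0, -80.0) == pf.chord_conductance(2.0, 80.0)
        assert pf.chord_conductance(4.0, -80.0) == 2 * pf.chord_conductance(2.0, -80.0)

    def test_zero_driving_force_rejected(self):
        with pytest.raises(pf.DomainError):
            pf.chord_conductance(2.0, 0.0, 0.0)


class TestSegmentBursts:
    def hand_record(self):
        # 7 events: open 1.0 / shut 0.2 / open 1.5 / shut 8 / open 0.5 /
        # shut 0.3 / open 2.0 (ms)
        return pf.IdealizedRecord(
            [
                Event("open", 1.0, 2.6),
                Event("shut", 0.2),
                Event("open", 1.5, 2.6),
                Event("shut", 8.0),
                Event("open", 0.5, 2.7),
                Event("shut", 0.3),
                Event("open", 2.0, 2.5),
            ],
            holding_potential=-100.0,
            filter_cutoff=2.0,
            resolution=50.0,
        )

    def test_hand_enumeration(self):
        bursts = pf.segment_bursts(self.hand_record(), tcrit=2.0)
        assert [b.n_openings for b in bursts.bursts] == [2, 2]
        # durations by hand: 1.0+0.2+1.5 = 2.7; 0.5+0.3+2.0 = 2.8
        assert bursts.bursts[0].duration == pytest.approx(2.7, rel=1e-12)
        assert bursts.bursts[1].duration == pytest.approx(2.8, rel=1e-12)

    def test_tcrit_limits(self):
        rec = self.hand_record()
        one = pf.segment_bursts(rec, tcrit=100.0)
        assert len(one) == 1 and one.bursts[0].n_openings == 4
        each = pf.segment_bursts(rec, tcrit=0.11)
        assert len(each) == 4

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        tcrit=st.floats(0.2, 50.0),
    )
    def test_conservation_and_monotonicity(self, seed, tcrit):
        rec, _ = simulate_single_channel(
            [replace(LOW_CONDUCTANCE_CLASS, mean_burst_duration=20.0,
                     mean_openings_per_burst=3.0, between_burst_gap_mean=60.0)],
            record_duration_s=2.0,
            seed=seed,
        )
        bursts = pf.segment_bursts(rec, tcrit)
        assert bursts.total_open_time() == pytest.approx(rec.total_open_time(), rel=1e-12)
        assert bursts.total_openings() == len(rec.openings)
        bigger = pf.segment_bursts(rec, tcrit * 2)
        assert len(bigger) <= len(bursts)


class TestBurstClassStats:
    def test_single_component_one_class(self):
        rec, _ = simulate_single_channel([LOW_CONDUCTANCE_CLASS], record_duration_s=20.0, seed=2)
        amps, _ = pf.filter_resolvable(rec)
        mix = pf.fit_amplitude_mixture(amps, k=1)
        stats = pf.burst_class_stats(pf.segment_bursts(rec, 5.0), mix)
        assert len(stats) == 1
        assert stats.iloc[0]["proportion"] == 1.0

    def test_outlier_burst_unassigned(self):
        mix = pf.AmplitudeMixture(
            components=[(2.6, 0.1, 0.3), (3.9, 0.1, 0.7)], n_openings_used=200
        )
        rec = record_from([(5.0, 10.0, None)], resolution=50.0)
        stats = pf.burst_class_stats(pf.segment_bursts(rec, 5.0), mix)
        assert list(stats["conductance_class"]) == ["unassigned"]

    def test_two_class_recovery_matches_generator(self):
        classes = [
            replace(LOW_CONDUCTANCE_CLASS, relative_frequency=0.3),
            replace(HIGH_CONDUCTANCE_CLASS, relative_frequency=0.7),
        ]
        rec, truth = simulate_single_channel(classes, record_duration_s=240.0, seed=13)
        amps, _ = pf.filter_resolvable(rec)
        mix = pf.fit_amplitude_mixture(amps, k=2)
        stats = pf.burst_class_stats(
            pf.segment_bursts(rec, 5.0), mix, rec.holding_potential
        ).set_index("conductance_class")
        lo, hi = stats.loc["class_0"], stats.loc["class_1"]
        # long low-conductance bursts vs short high-conductance bursts
        assert lo["mean_duration_ms"] == pytest.approx(
            100.0, abs=3 * lo["sem_duration_ms"] + 10.0
        )
        assert hi["mean_duration_ms"] == pytest.approx(
            14.0, abs=3 * hi["sem_duration_ms"] + 2.0
        )
        assert lo["mean_conductance_ps"] == pytest.approx(26.0, abs=2.5)
        assert hi["mean_conductance_ps"] == pytest.approx(39.0, abs=2.5)
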