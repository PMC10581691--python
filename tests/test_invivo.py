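"""In vivo spike-train analyses: PSTH, opto-tag, unit classes, down states,
rebound, rank order, state rates, stimulation modulation."""
import numpy as np
import pytest
from scipy.stats import kstest

from id2phys import invivo, synth
from id2phys.core import DomainError, InsufficientSpikesError, ShapeError, UnitRecord
from id2phys.invivo import (
    acg_tau_rise,
    assign_quantiles,
    classify_unit_waveform,
    compute_psth,
    detect_down_states,
    optotag_test,
    peri_down_response,
    rank_order,
    state_rates,
    stim_modulation,
    trough_to_peak,
)


def make_pulses(n=500, seed=0):
    rng = np.random.default_rng(seed)
    gaps = 0.4 + rng.uniform(-0.2, 0.2, size=n)
    pulses = 1.0 + np.cumsum(gaps)
    return pulses, float(pulses[-1] + 5.0)


class TestPsth:
    def test_silent_unit_flags_undefined_z(self):
        p = compute_psth(UnitRecord("u", np.array([])), np.arange(1.0, 50.0))
        assert np.all(p.rate_hz == 0)
        assert not p.z_defined and np.all(np.isnan(p.z))

    def test_empty_events_rejected(self):
        with pytest.raises(DomainError):
            compute_psth(UnitRecord("u", np.array([1.0])), np.array([]))

    def test_poisson_unit_rate_is_flat(self, rng):
        events = np.arange(1.0, 1001.0)
        unit = UnitRecord("u", synth.gen_poisson_train(10.0, 1002.0, rng))
        p = compute_psth(unit, events)
        assert np.all(np.abs(p.rate_hz - 10.0) < 3.5)  # ~3 sd of sqrt(10/(.01*1000))

    def test_planted_follower_dominates_one_bin(self, rng):
        events = np.arange(1.0, 301.0)
        spikes = np.sort(np.concatenate(
            [events + 0.005, synth.gen_poisson_train(1.0, 302.0, rng)]
        ))
        p = compute_psth(UnitRecord("u", spikes), events)
        assert p.bin_centers[np.argmax(p.rate_hz)] == pytest.approx(0.005, abs=0.005)


class TestOptoTag:
    def test_silent_unit_not_tagged_p_one(self):
        pulses, dur = make_pulses()
        r = optotag_test(UnitRecord("u", np.array([])), pulses, dur, seed=0)
        assert not r.tagged and r.p_shuffle == pytest.approx(1.0)

    def test_deterministic_follower_tagged_at_floor_p(self, rng):
        pulses, dur = make_pulses()
        spikes = np.sort(np.concatenate(
            [pulses + 0.005, synth.gen_poisson_train(2.0, dur, rng)]
        ))
        r = optotag_test(UnitRecord("u", spikes), pulses, dur, seed=1)
        assert r.tagged
        assert r.p_shuffle == pytest.approx(1.0 / 501.0)
        assert r.response_z > 2 and r.p_mod < 1e-3

    def test_too_few_pulses_forces_untagged(self, rng):
        unit = UnitRecord("u", synth.gen_poisson_train(5.0, 100.0, rng))
        with pytest.warns(UserWarning):
            r = optotag_test(unit, np.arange(1.0, 11.0), 100.0, seed=0)
        assert not r.tagged

    def test_null_units_control_type_one_error(self, rng):
        pulses, dur = make_pulses()
        tagged, ps = 0, []
        for i in range(150):
            u = UnitRecord("u", synth.gen_poisson_train(5.0, dur, rng))
            r = optotag_test(u, pulses, dur, seed=100 + i)
            tagged += r.tagged
            ps.append(r.p_shuffle)
        assert tagged <= 1
        # shuffle p-values approximately uniform on the null
        assert kstest(ps, "uniform").pvalue > 0.01


class TestWaveformClass:
    def test_template_trough_to_peak_by_construction(self):
        fs = 20000.0
        t = np.arange(int(0.003 * fs)) / fs * 1000.0
        w = -80 * np.exp(-0.5 * ((t - 1.0) / 0.1) ** 2) + 30 * np.exp(
            -0.5 * ((t - 1.8) / 0.3) ** 2
        )
        assert trough_to_peak(w, fs) == pytest.approx(0.8, abs=0.05)

    def test_flat_waveform_is_shape_error(self):
        with pytest.raises(ShapeError):
            trough_to_peak(np.zeros(50), 20000.0)

    def test_synthetic_class_templates_separate(self, rng):
        t2p = {c: trough_to_peak(*synth._class_waveform(c, rng)) for c in
               ("PC", "NW", "WW", "ID2")}
        assert t2p["NW"] < 0.425 < t2p["WW"] < t2p["PC"]

    @pytest.mark.parametrize(
        "t2p, tau, expected",
        [(0.3, 10.0, "NW"), (0.9, 30.0, "PC"), (0.9, 5.0, "WW")],
    )
    def test_classification_rules(self, t2p, tau, expected):
        assert classify_unit_waveform(t2p, tau) == expected


class TestAcg:
    def test_poisson_train_has_flat_acg(self, rng):
        tau = acg_tau_rise(synth.gen_poisson_train(10.0, 300.0, rng))
        assert tau < 2.0

    def test_refractory_recovery_tau_recovered(self):
        taus = [
            acg_tau_rise(
                synth.gen_refractory_train(8.0, 15.0, 1200.0,
                                           np.random.default_rng(s))
            )
            for s in range(4)
        ]
        assert np.mean(taus) == pytest.approx(15.0, abs=3.0)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(InsufficientSpikesError):
            acg_tau_rise(np.arange(0.0, 10.0, 0.1))


class TestDownStates:
    def test_planted_full_silences_recovered_within_25ms(self, rng):
        # 25 units, all silenced for 150 ms about once per second in NREM
        dur = 400.0
        downs = np.arange(5.0, dur - 5.0, 1.0) + rng.uniform(-0.1, 0.1,
                                                             size=390)
        units = []
        for i in range(25):
            sp = synth.gen_poisson_train(6.0, dur, rng)
            for d in downs:
                sp = sp[(sp < d - 0.075) | (sp > d + 0.075)]
            units.append(UnitRecord(f"u{i}", sp))
        from id2phys.core import IntervalSet

        nrem = IntervalSet.from_records([(0.0, dur, "NREM")])
        ds = detect_down_states(units, nrem, dur)
        det = ds.peaks.times
        dist = np.abs(downs[:, None] - det[None, :]).min(axis=1)
        assert np.mean(dist < 0.025) >= 0.90

    def test_constant_population_has_no_downs(self, rng):
        from id2phys.core import IntervalSet

        units = [UnitRecord(f"u{i}", synth.gen_poisson_train(8.0, 200.0, rng))
                 for i in range(25)]
        nrem = IntervalSet.from_records([(0.0, 200.0, "NREM")])
        assert len(detect_down_states(units, nrem, 200.0).peaks) == 0

    def test_short_silence_rejected_by_duration_filter(self, rng):
        from id2phys.core import IntervalSet

        dur = 200.0
        silence = 100.0
        units = []
        for i in range(25):
            sp = synth.gen_poisson_train(10.0, dur, rng)
            sp = sp[(sp < silence) | (sp > silence + 0.03)]  # 30 ms silence
            units.append(UnitRecord(f"u{i}", sp))
        nrem = IntervalSet.from_records([(0.0, dur, "NREM")])
        det = detect_down_states(units, nrem, dur).peaks.times
        assert not np.any(np.abs(det - (silence + 0.015)) < 0.05)

    def test_default_session_recall_and_precision(self, session_bundle):
        b = session_bundle
        di = np.array(b.ground_truth["down_intervals"])
        ds = detect_down_states(b.units, b.intervals, b.duration_s)
        det = ds.peaks.times
        covered = np.array([np.any((det >= a) & (det <= bb)) for a, bb in di])
        inside = np.array(
            [np.any((di[:, 0] <= p) & (p <= di[:, 1])) for p in det]
        )
        assert covered.mean() >= 0.9
        assert inside.mean() >= 0.9

    def test_requires_nrem_and_enough_units(self, rng):
        from id2phys.core import IntervalSet

        units = [UnitRecord(f"u{i}", synth.gen_poisson_train(5.0, 50.0, rng))
                 for i in range(25)]
        with pytest.raises(DomainError):
            detect_down_states(units[:5], IntervalSet.from_records(
                [(0, 50, "NREM")]), 50.0)
        with pytest.raises(DomainError):
            detect_down_states(units, IntervalSet.from_records([]), 50.0)


class TestPeriDown:
    def test_silenced_unit_has_negative_down_z_and_no_rebound(self, session_bundle):
        b = session_bundle
        peaks = np.array(b.ground_truth["down_peaks"])
        pc = next(u for u, i in zip(b.units, b.ground_truth["units"])
                  if i["cls"] == "PC")
        r = peri_down_response(pc, peaks)
        assert r.down_z < 0
        assert not r.rebound

    def test_planted_rebound_units_flagged_zero_gain_not(self, session_bundle):
        b = session_bundle
        ds = detect_down_states(b.units, b.intervals, b.duration_s)
        flags = {True: [], False: []}
        for u, info in zip(b.units, b.ground_truth["units"]):
            r = peri_down_response(u, ds.peaks)
            flags[info["rebound"]].append(r.rebound)
        assert all(flags[True])
        assert not any(flags[False])

    def test_stationary_poisson_z_trace_is_standardized(self, rng):
        unit = UnitRecord("u", synth.gen_poisson_train(6.0, 600.0, rng))
        peaks = np.sort(rng.uniform(1.0, 599.0, size=400))
        r = peri_down_response(unit, peaks)
        assert np.nanmean(r.psth.z) == pytest.approx(0.0, abs=0.35)
        assert np.nanstd(r.psth.z) == pytest.approx(1.0, abs=0.35)

    def test_too_few_down_peaks_rejected(self, rng):
        with pytest.raises(DomainError):
            peri_down_response(UnitRecord("u", np.array([1.0])),
                               np.arange(10.0))


class TestRankOrder:
    def _forced_units(self, offsets_ms, n_epochs=30):
        records, spikes = [], [[] for _ in offsets_ms]
        for e in range(n_epochs):
            a = 1.0 + e * 1.0
            records.append((a, a + 0.2, "UP"))
            for i, off in enumerate(offsets_ms):
                spikes[i].append(a + off / 1000.0)
        from id2phys.core import IntervalSet

        units = [UnitRecord(f"u{i}", np.array(s)) for i, s in enumerate(spikes)]
        return units, IntervalSet.from_records(records)

    def test_forced_ordering_gives_0_half_1(self):
        units, ups = self._forced_units([10.0, 20.0, 30.0])
        ranks = rank_order(units, ups, min_participants=2)
        np.testing.assert_allclose(ranks, [0.0, 0.5, 1.0])

    def test_invariant_to_translation_and_dilation(self):
        units, ups = self._forced_units([10.0, 20.0, 30.0, 40.0, 50.0])
        base = rank_order(units, ups)
        for f in (lambda t: t + 123.0, lambda t: t * 3.0):
            u2 = [UnitRecord(u.unit_id, f(u.spike_times)) for u in units]
            eps = ups.records()
            from id2phys.core import IntervalSet

            iv2 = IntervalSet.from_records([(f(a), f(b), l) for a, b, l in eps])
            np.testing.assert_allclose(rank_order(u2, iv2), base)

    def test_uniform_unit_centers_near_half(self):
        units, ups = synth.gen_rank_session(n_units=8, n_epochs=120,
                                            lead_ms=0.0, seed=3)
        ranks = rank_order(units, ups)
        assert np.all(np.abs(ranks - 0.5) < 0.12)

    def test_planted_early_unit_attains_minimum_rank(self):
        units, ups = synth.gen_rank_session(early_unit=2, seed=9)
        ranks = rank_order(units, ups)
        assert int(np.argmin(ranks)) == 2


class TestStateRates:
    def test_equal_rates_give_zero_index_and_cv(self, rng):
        from id2phys.core import IntervalSet

        iv = IntervalSet.from_records(
            [(0, 50, "RUN"), (50, 100, "QUIET"), (100, 150, "NREM"),
             (150, 200, "REM")]
        )
        unit = UnitRecord("u", np.arange(0.05, 200.0, 0.2))  # exact 5 Hz
        r = state_rates(unit, iv)
        assert r.sleep_awake_index == pytest.approx(0.0, abs=1e-9)
        assert r.rate_cv == pytest.approx(0.0, abs=1e-9)

    def test_index_formula_by_hand(self):
        from id2phys.core import IntervalSet

        iv = IntervalSet.from_records(
            [(0, 100, "RUN"), (100, 200, "QUIET"), (200, 300, "NREM"),
             (300, 400, "REM")]
        )
        spikes = np.concatenate([
            np.arange(0.1, 200.0, 1.0 / 3.0),       # awake at 3 Hz
            np.arange(200.1, 400.0, 1.0),           # sleep at 1 Hz
        ])
        r = state_rates(UnitRecord("u", np.sort(spikes)), iv)
        assert r.sleep_awake_index == pytest.approx(0.5, abs=0.02)

    def test_zero_spikes_flagged_undefined(self):
        from id2phys.core import IntervalSet

        iv = IntervalSet.from_records(
            [(0, 50, "RUN"), (50, 100, "QUIET"), (100, 150, "NREM"),
             (150, 200, "REM")]
        )
        r = state_rates(UnitRecord("u", np.array([])), iv)
        assert np.isnan(r.sleep_awake_index) and r.flags

    def test_id2_units_have_near_zero_index_in_default_session(self, session_bundle):
        b = session_bundle
        idx = [
            state_rates(u, b.intervals).sleep_awake_index
            for u, info in zip(b.units, b.ground_truth["units"])
            if info["cls"] == "ID2"
        ]
        assert abs(np.mean(idx)) < 0.12


class TestStimModulation:
    @staticmethod
    def _modulated_unit(kind, pulses, dur, rng, base_hz=8.0):
        """Poisson unit with a planted per-pulse rate modulation."""
        grid = 0.001
        rate = np.full(int(dur / grid), base_hz)
        for p in pulses:
            if kind == "neg":        # rate x 0.2 for 80 ms post pulse
                rate[int(p / grid): int((p + 0.08) / grid)] *= 0.2
            elif kind == "pos":      # rate x 2 from +60 to +160 ms
                rate[int((p + 0.06) / grid): int((p + 0.16) / grid)] *= 2.0
        c = rng.poisson(rate * grid)
        t = (np.flatnonzero(c) + rng.uniform(0, 1, size=np.count_nonzero(c))) * grid
        return UnitRecord(kind, np.sort(t))

    def test_planted_single_unit_constructions(self, rng):
        pulses = 10.0 + np.cumsum(1.0 + rng.uniform(-0.2, 0.2, 300))
        dur = float(pulses[-1] + 10.0)
        r_neg = stim_modulation(
            self._modulated_unit("neg", pulses, dur, rng), pulses, dur, seed=1
        )
        r_pos = stim_modulation(
            self._modulated_unit("pos", pulses, dur, rng), pulses, dur, seed=2
        )
        r_non = stim_modulation(
            self._modulated_unit("none", pulses, dur, rng), pulses, dur, seed=3
        )
        assert r_neg.mod_class == "neg"
        assert r_pos.mod_class == "pos"
        assert r_non.mod_class == "none"
        # slow facilitation peaks later than fast suppression
        assert r_pos.peak_latency_ms > r_neg.peak_latency_ms

    def test_session_modulation_recovery(self, session_bundle):
        b = session_bundle
        pulses = b.events["pulse"]
        got = {"neg": [], "pos": [], "none": []}
        for i, (u, info) in enumerate(zip(b.units, b.ground_truth["units"])):
            if info["mod"] == "tagged":
                continue
            r = stim_modulation(u, pulses, b.duration_s, seed=500 + i,
                                null_jitter_s=5.0)
            got[info["mod"]].append(r)
        assert np.mean([r.mod_class == "neg" for r in got["neg"]]) >= 0.8
        assert np.mean([r.mod_class == "none" for r in got["none"]]) >= 0.7
        # the planted slow facilitation is weak through the 0-100 ms window
        # but its sign and its later peak must still be resolved
        if got["pos"]:
            assert np.mean([r.resp_0_100 for r in got["pos"]]) > 1.0
            assert np.mean([r.peak_latency_ms for r in got["pos"]]) > np.mean(
                [r.peak_latency_ms for r in got["neg"]]
            )

    def test_quantiles_partition_into_equal_groups(self, rng):
        q = assign_quantiles(rng.normal(size=100))
        counts = np.bincount(q)[1:]
        assert np.all(counts == 20)
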