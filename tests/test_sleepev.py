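"""Sleep event detection, coupling, and circular statistics."""

import numpy as np
import pytest

from seqsleep.sleepev import (
    PhaseSet,
    SleepRecord,
    SlowOscillation,
    Spindle,
    bandpass,
    couple_events,
    detect_sos,
    detect_spindles,
    ppc,
    rayleigh_test,
    so_phases_at_spindles,
    stage_proportions,
)


def make_record(signal, fs=100.0):
    n_ep = int(np.ceil(len(signal) / fs / 30.0))
    return SleepRecord(
        signal=np.asarray(signal)[None, :],
        sample_rate=fs,
        stages=tuple(["N2"] * n_ep),
        ch_names=("Cz",),
    )


def match_events(truth_df, events, tol=0.3):
    """Recall and mean onset error of truth events against detections."""
    hits, errs = 0, []
    for row in truth_df.itertuples():
        cands = [e for e in events if abs(e.onset - row.onset) < tol]
        if cands:
            hits += 1
            errs.append(min(abs(e.onset - row.onset) for e in cands))
    return hits / len(truth_df), (float(np.mean(errs)) if errs else np.inf)


class TestSODetection:
    def test_slow_sinusoid_rejected_by_duration(self):
        # 0.4 Hz: each cycle lasts 2.5 s, outside the 0.8-2 s band
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        rec = make_record(50 * np.sin(2 * np.pi * 0.4 * t), fs)
        assert detect_sos(rec) == []

    def test_identical_candidates_none_exceed_threshold(self, monkeypatch):
        # every candidate has exactly the same amplitude, so none strictly
        # exceeds mean + 1 s.d.; the band-pass is patched to the identity so
        # filter edge ripple cannot break the exact tie
        import seqsleep.sleepev as sleepev

        monkeypatch.setattr(
            sleepev, "bandpass", lambda x, band, fs, order=3: np.asarray(x, float)
        )
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)  # 0.5 Hz: integer samples per period
        rec = make_record(50 * np.sin(2 * np.pi * 0.5 * t), fs)
        assert detect_sos(rec) == []

    def test_injected_events_recovered(self, sleep_record):
        record, truth, _ = sleep_record
        sos = detect_sos(record)
        recall, onset_err = match_events(truth.sos, sos)
        assert recall >= 0.9
        assert onset_err <= 0.1
        for e in sos:
            assert 0.8 <= e.duration <= 2.0

    def test_empty_nrem_mask_rejected(self, sleep_record):
        record, _, _ = sleep_record
        with pytest.raises(ValueError, match="NREM"):
            detect_sos(record, nrem_mask=np.zeros(record.n_samples, bool))


class TestSpindleDetection:
    def test_injected_bursts_recovered(self, sleep_record):
        record, truth, _ = sleep_record
        sp = detect_spindles(record)
        recall, onset_err = match_events(truth.spindles, sp)
        assert recall >= 0.9
        assert onset_err <= 0.1
        for e in sp:
            assert 0.4 <= e.duration <= 3.0
            assert e.n_cycles >= 6

    def test_short_burst_rejected(self):
        fs = 100.0
        t = np.arange(0, 90, 1 / fs)
        rng = np.random.default_rng(0)
        sig = 2.0 * rng.normal(size=t.size)
        sel = (t >= 45.0) & (t < 45.2)  # 0.2 s, below the 0.4 s minimum
        sig[sel] += 40 * np.sin(2 * np.pi * 13.5 * t[sel])
        assert detect_spindles(make_record(sig, fs)) == []

    def test_artifact_rule_rejects_extreme_burst(self):
        # several ordinary bursts set the scale; one burst is so large that
        # its envelope exceeds mean + 9 s.d. and must be discarded
        fs = 100.0
        t = np.arange(0, 300, 1 / fs)
        rng = np.random.default_rng(1)
        sig = 2.0 * rng.normal(size=t.size)
        onsets = np.arange(20.0, 280.0, 15.0)
        for i, on in enumerate(onsets):
            sel = (t >= on) & (t < on + 1.0)
            amp = 150.0 if i == 0 else 35.0
            sig[sel] += amp * np.sqrt(np.hanning(sel.sum())) * np.sin(
                2 * np.pi * 13.5 * t[sel]
            )
        sp = detect_spindles(make_record(sig, fs))
        assert len(sp) > 0
        assert all(abs(e.onset - onsets[0]) > 1.0 for e in sp)

    def test_too_few_cycles_rejected(self, monkeypatch):
        # With the identity filter (so band-pass smearing cannot add cycles),
        # a 0.45 s 11 Hz burst holds 5 positive peaks: below the 6 required,
        # while a 13.5 Hz burst of the same length passes.
        import seqsleep.sleepev as sleepev

        monkeypatch.setattr(
            sleepev, "bandpass", lambda x, band, fs, order=3: np.asarray(x, float)
        )
        fs = 200.0
        t = np.arange(0, 180, 1 / fs)
        onsets = np.arange(20.0, 170.0, 15.0)
        for f0, expect_some in [(11.0, False), (13.5, True)]:
            sig = np.zeros(t.size)
            for on in onsets:  # identical bursts keep the 9 s.d. rule quiet
                sel = (t >= on) & (t < on + 0.45)
                sig[sel] += 30 * np.sin(2 * np.pi * f0 * (t[sel] - on))
            sp = detect_spindles(make_record(sig, fs))
            if expect_some:
                assert len(sp) == len(onsets)
                assert all(e.n_cycles >= 6 for e in sp)
            else:
                assert sp == []  # only 5 positive peaks per burst


class TestCoupling:
    def _so(self, onset, offset):
        return SlowOscillation(onset, offset, 80.0, 150.0, "Cz")

    def _sp(self, center, half=0.4):
        return Spindle(center - half, center + half, center, 10, "Cz")

    def test_center_inside_so_pairs(self):
        pairs = couple_events([self._so(10.0, 11.2)], [self._sp(10.6)])
        assert len(pairs) == 1

    def test_center_after_offset_no_pair(self):
        assert couple_events([self._so(10.0, 11.2)], [self._sp(11.3)]) == []

    def test_two_spindles_in_one_so_two_pairs(self):
        pairs = couple_events([self._so(10.0, 11.9)], [self._sp(10.4), self._sp(11.5)])
        assert len(pairs) == 2

    def test_mixed_channels_rejected(self):
        sp = Spindle(9.6, 10.4, 10.0, 8, "Fz")
        with pytest.raises(ValueError, match="single channel"):
            couple_events([self._so(9.0, 10.5)], [sp])


class TestPhases:
    def _sine_record(self, f0=0.75, fs=100.0, dur=120.0):
        t = np.arange(0, dur, 1 / fs)
        return make_record(60 * np.sin(2 * np.pi * f0 * t), fs), t

    def test_phase_zero_at_up_state_peak(self):
        rec, t = self._sine_record()
        # peak of sin at t = 1/(4 f0) + k/f0
        peak = 1 / (4 * 0.75) + 30 / 0.75
        so = SlowOscillation(peak - 0.5, peak + 0.5, 60, 120, "Cz")
        sp = Spindle(peak - 0.3, peak + 0.3, peak, 8, "Cz")
        phases = so_phases_at_spindles(rec, "Cz", [(so, sp)])
        assert abs(phases.phases[0]) < 0.15

    def test_phase_pi_at_trough(self):
        rec, t = self._sine_record()
        trough = 3 / (4 * 0.75) + 30 / 0.75
        sp = Spindle(trough - 0.3, trough + 0.3, trough, 8, "Cz")
        so = SlowOscillation(trough - 0.5, trough + 0.5, 60, 120, "Cz")
        phases = so_phases_at_spindles(rec, "Cz", [(so, sp)])
        assert abs(abs(phases.phases[0]) - np.pi) < 0.15

    def test_phase_advances_quarter_period_after_peak(self):
        rec, t = self._sine_record()
        peak = 1 / (4 * 0.75) + 30 / 0.75
        quarter = peak + 1 / (4 * 0.75)
        sp = Spindle(quarter - 0.3, quarter + 0.3, quarter, 8, "Cz")
        so = SlowOscillation(quarter - 0.5, quarter + 0.5, 60, 120, "Cz")
        phases = so_phases_at_spindles(rec, "Cz", [(so, sp)])
        assert phases.phases[0] == pytest.approx(np.pi / 2, abs=0.15)

    def test_center_outside_record_rejected(self):
        rec, _ = self._sine_record(dur=90.0)
        sp = Spindle(199.6, 200.4, 200.0, 8, "Cz")
        so = SlowOscillation(199.0, 201.0, 60, 120, "Cz")
        with pytest.raises(ValueError, match="outside"):
            so_phases_at_spindles(rec, "Cz", [(so, sp)])


class TestPPC:
    def test_identical_phases(self):
        assert ppc(np.full(17, 1.3)) == pytest.approx(1.0)

    def test_two_opposite_phases(self):
        assert ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0)

    def test_four_cardinal_phases(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert ppc(phases) == pytest.approx(-1.0 / 3.0)

    def test_matches_bruteforce_pairwise_enumeration(self):
        rng = np.random.default_rng(5)
        phi = rng.uniform(-np.pi, np.pi, size=23)
        brute = np.mean(
            [np.cos(phi[i] - phi[j]) for i in range(23) for j in range(23) if i != j]
        )
        assert ppc(phi) == pytest.approx(brute, abs=1e-12)

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ppc(np.array([0.3]))

    def test_unbiased_across_sample_sizes(self):
        # mean PPC estimates the squared population resultant length,
        # independent of the number of events
        from scipy.special import i0, i1

        kappa = 3.0
        target = (i1(kappa) / i0(kappa)) ** 2
        rng = np.random.default_rng(7)
        for n in (10, 50, 200):
            est = np.mean(
                [ppc(rng.vonmises(0.0, kappa, size=n)) for _ in range(300)]
            )
            assert est == pytest.approx(target, abs=0.04)


class TestRayleigh:
    def test_identical_phases_reject_uniformity(self):
        R, p = rayleigh_test(np.full(10, 0.7))
        assert R == pytest.approx(1.0)
        assert p < 1e-3

    def test_even_grid_is_uniform(self):
        R, p = rayleigh_test(np.linspace(-np.pi, np.pi, 12, endpoint=False))
        assert R == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_von_mises_sample_rejects(self):
        rng = np.random.default_rng(3)
        R, p = rayleigh_test(rng.vonmises(0.0, 5.0, size=100))
        assert p < 1e-6

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        phi = rng.vonmises(1.0, 1.5, size=40)
        _, p = rayleigh_test(phi)
        _, p_ref = pingouin.circ_rayleigh(phi)
        assert p == pytest.approx(p_ref, rel=0.05, abs=1e-4)


class TestStageProportions:
    def test_all_sws(self):
        props = stage_proportions(["SWS"] * 6)
        assert props["SWS"] == 1.0
        assert sum(props.values()) == pytest.approx(1.0)

    def test_even_split(self):
        props = stage_proportions(["N2", "SWS"] * 5)
        assert props["N2"] == props["SWS"] == 0.5

    def test_hand_counted_hypnogram(self):
        stages = ["W", "W", "N1", "N2", "N2", "N2", "SWS", "SWS", "REM", "N2"]
        props = stage_proportions(stages)
        assert props == {
            "W": 0.2, "N1": 0.1, "N2": 0.4, "SWS": 0.2, "REM": 0.1,
        }
        no_wake = stage_proportions(stages, include_wake=False)
        assert no_wake["N2"] == pytest.approx(4 / 8)
        assert no_wake["W"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stage_proportions([])
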