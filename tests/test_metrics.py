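"""Response metrics: windows, sparseness, best frequency, ranked fits, flags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icophys import AnalysisError, ParameterError
from icophys import metrics as M
from icophys import simulate as S
from icophys import stimuli as X

from conftest import regular_spikes


class TestIsiViolations:
    def test_regular_train_is_clean(self):
        assert M.isi_violation_rate(np.arange(0, 1, 0.010)) == 0.0

    def test_planted_violations_counted(self):
        spikes = np.arange(100) * 0.010
        spikes[10] = spikes[9] + 0.0005
        spikes[50] = spikes[49] + 0.0005
        spikes[90] = spikes[89] + 0.0005
        spikes = np.sort(spikes)
        assert M.isi_violation_rate(spikes) == pytest.approx(3 / 99)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 10, 500))
        brute = sum(
            1 for a, b in zip(spikes[:-1], spikes[1:]) if b - a < 0.001
        ) / (spikes.size - 1)
        assert M.isi_violation_rate(spikes) == pytest.approx(brute)

    def test_too_few_spikes_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert M.isi_violation_rate(np.array([0.1])) == 0.0


class TestPSTH:
    def test_single_spike_single_trial(self, small_sched):
        onset = small_sched.events[0].onset
        rates, edges = M.psth(
            np.array([onset + 0.010]),
            small_sched, window=(0.0, 0.03), binsize=0.005,
        )
        # all trials but one are empty; the spike lands in bin [10, 15) ms
        hot = int(np.nonzero(rates)[0][0])
        assert edges[hot] == pytest.approx(0.010)
        assert rates[hot] == pytest.approx(1 / (len(small_sched.events) * 0.005))

    def test_homogeneous_rate_flat(self, small_sched):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, small_sched.total_duration,
                                     int(40 * small_sched.total_duration)))
        rates, _ = M.psth(spikes, small_sched, window=(-0.04, 0.06), binsize=0.02)
        assert rates.mean() == pytest.approx(40.0, abs=4.0)
        np.testing.assert_allclose(rates, 40.0, atol=22.0)

    def test_empty_filter_errors(self, small_sched):
        with pytest.raises(AnalysisError, match="laser"):
            M.psth(np.array([0.1]), small_sched, frequencies=np.array([1.0]), laser=True)

    def test_peak_near_onset_latency(self, small_sched, small_grid):
        u = S.GroundTruthUnit(unit_id="u", spont_rate=2.0, bf=12000.0,
                              peak_evoked=80.0, onset_latency=0.015)
        rec = S.simulate_tone_session([u], small_sched, seed=1)
        rates, edges = M.psth(rec.units["u"], small_sched, window=(0.0, 0.05),
                              binsize=0.005)
        # box-shaped drive: response onset (first elevated bin), not argmax,
        # marks the latency
        onset_bin = edges[int(np.argmax(rates > 2.0 + 0.5 * (rates.max() - 2.0)))]
        assert abs(onset_bin - 0.015) <= 0.005


class TestTopFrequencies:
    def test_monotone_curve(self):
        tc = M.TuningCurve(np.arange(1, 51) * 1000.0, np.arange(50.0), "laser_off", 10)
        assert list(M.top_frequencies(tc, 7)) == list(range(43, 50))

    def test_all_equal_tie_rule(self):
        tc = M.TuningCurve(np.arange(1, 51) * 1000.0, np.ones(50), "laser_off", 10)
        assert list(M.top_frequencies(tc, 7)) == list(range(7))

    def test_brackets_simulated_bf(self, small_sched):
        u = S.GroundTruthUnit(unit_id="u", spont_rate=1.0, bf=12000.0,
                              peak_evoked=60.0, bandwidth=0.4)
        rec = S.simulate_tone_session([u], small_sched, seed=2)
        tc = M.tuning_curve(rec.units["u"], small_sched, laser=False)
        idx = M.top_frequencies(tc, 5)
        bf_idx = int(np.argmin(np.abs(tc.freqs - 12000.0)))
        assert idx.min() <= bf_idx <= idx.max()


class TestSelection:
    def test_untuned_unit_excluded(self, small_sched):
        u = S.GroundTruthUnit(unit_id="u", spont_rate=8.0, peak_evoked=0.0)
        rec = S.simulate_tone_session([u], small_sched, seed=3)
        table = M.select_responsive(rec, small_sched)
        assert not table.loc["u", "responsive"]

    def test_strong_unit_retained(self, small_sched):
        u = S.GroundTruthUnit(unit_id="u", spont_rate=2.0, bf=12000.0,
                              peak_evoked=120.0, bandwidth=0.6, onset_latency=0.005)
        rec = S.simulate_tone_session([u], small_sched, seed=4)
        table = M.select_responsive(rec, small_sched)
        assert table.loc["u", "responsive"]

    def test_silent_unit_flagged_degenerate(self, small_sched):
        rec = S.SpikeRecording(units={"u": np.empty(0)},
                               duration=small_sched.total_duration)
        table = M.select_responsive(rec, small_sched)
        assert not table.loc["u", "responsive"] and table.loc["u", "degenerate"]


class TestWindowsAndDecomposition:
    def test_constant_rate_both_conditions(self, small_sched):
        spikes = regular_spikes(50.0, small_sched.total_duration)
        top = np.unique([e.frequency for e in small_sched.events])[:7]
        tt = M.trial_table(small_sched)
        for laser in (False, True):
            sub = tt[(tt.laser == laser) & np.isin(tt.frequency, top)]
            # the trial at onset 0 has an empty (pre-session) window
            expect = 50.0 * (sub.onset > 0).mean()
            r = M.spontaneous_rate(spikes, small_sched, laser=laser, top_freqs=top)
            assert r == pytest.approx(expect, abs=1e-9)

    def test_decomposition_identity(self, small_sched):
        """evoked_magnitude + spontaneous_rate == raw 75 ms window rate."""
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(0, small_sched.total_duration, 2000))
        tc = M.tuning_curve(spikes, small_sched, laser=False)
        top = tc.freqs[M.top_frequencies(tc, 7)]
        for laser in (False, True):
            mag = M.evoked_magnitude(spikes, small_sched, laser=laser, top_freqs=top)
            sp = M.spontaneous_rate(spikes, small_sched, laser=laser, top_freqs=top)
            raw = np.mean(M._condition_trial_rates(
                spikes, small_sched, laser, (0.0, 0.075), top, 7))
            assert mag + sp == pytest.approx(raw, abs=1e-9)

    def test_agrees_with_brute_force_counter(self, small_sched):
        """Windowed rates match a per-trial python loop on a hand-built train."""
        rng = np.random.default_rng(6)
        spikes = np.sort(rng.uniform(0, small_sched.total_duration, 800))
        onsets = [e.onset for e in small_sched.events if e.laser]
        rates = M.window_rates(spikes, np.array(onsets), -0.02, 0.0)
        brute = [
            sum(1 for t in spikes if o - 0.02 <= t < o) / 0.02 for o in onsets
        ]
        np.testing.assert_allclose(rates, brute)


class TestSparseness:
    @pytest.mark.parametrize(
        "fr,expected",
        [
            (np.full(50, 7.3), 0.0),                 # uniform -> 0
            (np.eye(50)[0] * 11.0, 1 - 1 / 50),      # one-hot, n=50 -> 0.98
            (np.array([3.0, 1.0]), 0.2),             # hand arithmetic
        ],
    )
    def test_exact_values(self, fr, expected):
        assert M.sparseness(fr) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(M.sparseness(np.zeros(10)))

    @given(
        fr=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=60),
        scale=st.floats(0.01, 50.0),
        shift=st.floats(0.1, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_scale_invariance_and_baseline_monotonicity(self, fr, scale, shift):
        fr = np.asarray(fr)
        if np.sum(fr**2) == 0:  # all-zero (or squares underflow): undefined
            return
        s = M.sparseness(fr)
        n = fr.size
        assert 0.0 - 1e-12 <= s <= 1 - 1 / n + 1e-12
        assert M.sparseness(fr * scale) == pytest.approx(s, abs=1e-9)
        if np.ptp(fr) > 0:
            assert s > 0
            # adding a constant baseline reduces selectivity
            assert M.sparseness(fr + shift) < s + 1e-12
        else:
            assert s == pytest.approx(0.0, abs=1e-12)


class TestBestFrequency:
    def test_max_and_tie_rule(self):
        freqs = np.array([1000.0, 2000.0, 4000.0, 8000.0])
        tc = M.TuningCurve(freqs, np.array([1.0, 5.0, 5.0, 2.0]), "laser_off", 10)
        assert M.best_frequency(tc) == 2000.0

    def test_simulated_bf_recovered(self, small_sched):
        hits = 0
        for seed in range(10):
            u = S.GroundTruthUnit(unit_id="u", spont_rate=2.0, bf=12000.0,
                                  peak_evoked=60.0, bandwidth=0.4)
            rec = S.simulate_tone_session([u], small_sched, seed=seed)
            tc = M.tuning_curve(rec.units["u"], small_sched, laser=False)
            bf = M.best_frequency(tc)
            step = np.log2(tc.freqs[1] / tc.freqs[0])
            hits += abs(np.log2(bf / 12000.0)) <= step * 1.5
        assert hits >= 9


class TestRankedFit:
    def test_identity(self):
        freqs = np.arange(1, 51) * 1000.0
        fr = np.random.default_rng(7).uniform(0, 30, 50)
        off = M.TuningCurve(freqs, fr, "laser_off", 10)
        on = M.TuningCurve(freqs, fr.copy(), "laser_on", 10)
        fit = M.ranked_linear_fit(off, on)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_exact_affine_relation(self):
        freqs = np.arange(1, 51) * 1000.0
        fr = np.random.default_rng(8).uniform(1, 30, 50)
        off = M.TuningCurve(freqs, fr, "laser_off", 10)
        on = M.TuningCurve(freqs, 0.5 * fr + 2.0, "laser_on", 10)
        fit = M.ranked_linear_fit(off, on)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)

    def test_zero_variance_degenerate(self):
        freqs = np.arange(1, 11) * 1000.0
        off = M.TuningCurve(freqs, np.ones(10), "laser_off", 5)
        on = M.TuningCurve(freqs, np.arange(10.0), "laser_on", 5)
        with pytest.warns(UserWarning):
            fit = M.ranked_linear_fit(off, on)
        assert fit.degenerate and np.isnan(fit.slope)

    def test_null_slope_calibration(self, small_sched):
        """Rank-matched fits of identically distributed conditions: slope ~ 1."""
        slopes = []
        for seed in range(8):
            u = S.GroundTruthUnit(unit_id="u", spont_rate=4.0, bf=12000.0,
                                  peak_evoked=40.0, bandwidth=0.5)
            rec = S.simulate_tone_session([u], small_sched, seed=seed)
            off = M.tuning_curve(rec.units["u"], small_sched, laser=False)
            on = M.tuning_curve(rec.units["u"], small_sched, laser=True)
            slopes.append(M.ranked_linear_fit(off, on).slope)
        assert np.median(slopes) == pytest.approx(1.0, abs=0.15)


class TestUnitMetricsAndStratification:
    def test_identical_conditions_no_flags(self, small_sched):
        """A perfectly regular train gives exactly equal ON/OFF values."""
        spikes = regular_spikes(20.0, small_sched.total_duration)
        rec = S.SpikeRecording(units={"u": spikes}, duration=small_sched.total_duration)
        mt = M.compute_unit_metrics(rec, small_sched)
        row = mt.loc["u"]
        assert row.spont_on == row.spont_off
        assert not (row.spont_increase or row.spont_decrease
                    or row.mag_increase or row.mag_decrease)

    def test_large_offset_flags_spont_increase(self, small_grid):
        sched = X.make_tone_schedule(small_grid, n_repeats=20, seed=9)
        mod = S.ModulationModel(spont_delta=40.0)
        units = [
            S.GroundTruthUnit(unit_id=f"u{i}", spont_rate=4.0, bf=12000.0,
                              peak_evoked=30.0, modulation=mod)
            for i in range(10)
        ]
        rec = S.simulate_tone_session(units, sched, seed=10)
        mt = M.compute_unit_metrics(rec, sched)
        assert mt.spont_increase.mean() >= 0.9

    def test_stratify_transfers_reference_flags(self, small_sched, modulated_population):
        rec = S.simulate_tone_session(modulated_population[:5], small_sched, seed=11)
        ref = M.compute_unit_metrics(rec, small_sched)
        other = ref.drop(columns=["spont_increase"])  # pretend another onset
        merged = M.stratify_units(ref, other)
        assert (merged.spont_increase == ref.spont_increase).all()


class TestClickResponse:
    def test_rates_and_conditions(self):
        sched = X.make_click_schedule(n_trains=10)
        dur = sched.total_duration
        spikes = regular_spikes(30.0, dur)
        rec = S.SpikeRecording(units={"u": spikes}, duration=dur)
        resp = M.click_response(rec, sched)
        assert set(resp.condition) == {"laser_on", "laser_off"}
        np.testing.assert_allclose(resp.evoked_rate, 30.0, atol=2.5)
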