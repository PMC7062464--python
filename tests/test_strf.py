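"""STRF estimation: chunking, upsampling, STA oracle, significance, lobes."""

import numpy as np
import pytest

from icophys import AnalysisError, ParameterError
from icophys import simulate as S
from icophys import stimuli as X
from icophys import strf as R


def brute_force_strf(spikes, drc, condition, max_lag=0.1, lag_bin=0.005):
    """Independent per-spike loop STA with per-file spike-count weighting."""
    L = int(round(max_lag / lag_bin))
    rep = int(round(drc.chord_duration / lag_bin))
    dev = np.repeat(drc.chord_levels - drc.mean_level, rep, axis=0)
    n_bins = dev.shape[0]
    want_on = condition == "laser_on"

    def chunk_of(b):
        """(kind, start_bin) for bin b, or None."""
        t = b * lag_bin
        cyc = int(t // drc.laser_period)
        on0 = cyc * drc.laser_period + drc.laser_onset_offset
        if on0 <= t < on0 + drc.laser_duration:
            return "on", int(round(on0 / lag_bin))
        if on0 - drc.laser_duration <= t < on0:
            return "off", int(round((on0 - drc.laser_duration) / lag_bin))
        return None

    per_file_windows: dict[int, list] = {}
    for t in spikes:
        b = int(t / lag_bin)
        if not (0 <= b < n_bins):
            continue
        ck = chunk_of(b)
        if ck is None or ck[0] != ("on" if want_on else "off"):
            continue
        if b - L < ck[1]:
            continue  # history crosses the chunk boundary
        win = np.stack([dev[b - 1 - l] for l in range(L)])
        f = min(int(t / drc.file_duration), drc.n_files - 1)
        per_file_windows.setdefault(f, []).append(win)

    total = sum(len(v) for v in per_file_windows.values())
    out = np.zeros((L, drc.freqs.n_freqs))
    for f, wins in per_file_windows.items():
        # bias: mean window over every valid anchor bin of this file/condition
        anchors = []
        for b in range(n_bins):
            if min(int(b * lag_bin / drc.file_duration), drc.n_files - 1) != f:
                continue
            ck = chunk_of(b)
            if ck is None or ck[0] != ("on" if want_on else "off"):
                continue
            if b - L >= ck[1]:
                anchors.append(b)
        bias = np.mean(
            [np.stack([dev[b - 1 - l] for l in range(L)]) for b in anchors], axis=0
        )
        out += len(wins) * (np.mean(wins, axis=0) - bias)
    return out / total, total


class TestChunking:
    def test_ten_second_example(self, drc_grid):
        drc = X.make_drc(drc_grid, total_dur=10.0, n_files=1, seed=1)
        seg = R.segment_laser_chunks(drc, np.array([]))
        assert len(seg.on_chunks) == 10 and len(seg.off_chunks) == 10
        np.testing.assert_allclose(seg.on_chunks[:, 1] - seg.on_chunks[:, 0], 0.25)
        np.testing.assert_allclose(seg.off_chunks[:, 1], seg.on_chunks[:, 0])

    def test_spike_assignment_and_conservation(self, drc_grid):
        drc = X.make_drc(drc_grid, total_dur=10.0, n_files=1, seed=1)
        # laser ON at [0.75, 1.0); OFF chunk [0.5, 0.75)
        spikes = np.array([0.1, 0.6, 0.8, 1.2, 9.9])
        seg = R.segment_laser_chunks(drc, spikes)
        assert seg.n_off == 1 and seg.n_on == 2  # 0.6 OFF; 0.8 and 9.9 ON
        assert seg.n_discarded == 2              # 0.1 and 1.2 in neither
        assert seg.n_on + seg.n_off + seg.n_discarded == spikes.size

    def test_no_spikes(self, tiny_drc):
        seg = R.segment_laser_chunks(tiny_drc, np.array([]))
        assert seg.n_on == seg.n_off == seg.n_discarded == 0
        with pytest.raises(AnalysisError):
            R.estimate_strf(np.array([]), tiny_drc, "laser_off")


class TestUpsample:
    def test_replication_and_identity(self, tiny_drc):
        up = R.upsample_drc(tiny_drc, 0.005)
        assert up.shape[0] == tiny_drc.n_chords * 4
        dev = tiny_drc.level_deviations()
        np.testing.assert_array_equal(up[0::4], dev)
        np.testing.assert_array_equal(up[3::4], dev)
        ident = R.upsample_drc(tiny_drc, tiny_drc.chord_duration)
        np.testing.assert_array_equal(ident, dev)
        # column sums scale exactly by the replication factor
        np.testing.assert_allclose(up.sum(0), 4 * dev.sum(0), rtol=1e-12)

    def test_non_divisible_bin_rejected(self, tiny_drc):
        with pytest.raises(ParameterError):
            R.upsample_drc(tiny_drc, 0.003)


class TestEstimator:
    @pytest.mark.parametrize("condition", ["laser_off", "laser_on"])
    def test_matches_brute_force_oracle(self, drc_grid, condition):
        """Vectorized estimator == literal per-spike loop to 1e-10 (10 s)."""
        drc = X.make_drc(drc_grid, total_dur=10.0, n_files=2, seed=2)
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 10.0, 400))
        with pytest.warns(UserWarning):
            est = R.estimate_strf(spikes, drc, condition)
        oracle, n = brute_force_strf(spikes, drc, condition)
        assert est.n_spikes == n
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_null_unit_near_zero(self, drc_grid):
        """Stimulus-independent spikes: all pixels within 4 SE of zero."""
        drc = X.make_drc(drc_grid, total_dur=240.0, n_files=2, seed=4)
        u = S.GroundTruthUnit(unit_id="u", spont_rate=20.0,
                              strf_true=np.zeros((20, 50)))
        rec = S.simulate_drc_session([u], drc, seed=5)
        est = R.estimate_strf(rec.units["u"], drc, "laser_off")
        # per-pixel SE ~ level SD / sqrt(effective n); chord replication
        # (4 bins/chord) reduces the effective sample by up to 4x
        se = 20.0 / np.sqrt(est.n_spikes / 4)
        assert np.abs(est.values).max() < 4 * se

    def test_planted_peak_recovery(self, drc_grid):
        drc = X.make_drc(drc_grid, total_dur=300.0, n_files=2, seed=6)
        shape = S.make_gaussian_strf(20, 50, 9, 17)
        amp = S._strf_amplitude_for_sd(shape, 20.0, 4, 10.0)
        u = S.GroundTruthUnit(unit_id="u", spont_rate=12.0, strf_true=shape * amp)
        rec = S.simulate_drc_session([u], drc, seed=7)
        for cond in ("laser_off", "laser_on"):
            est = R.estimate_strf(rec.units["u"], drc, cond)
            peak = np.unravel_index(np.argmax(est.values), est.values.shape)
            assert abs(peak[0] - 9) <= 1 and abs(peak[1] - 17) <= 1


class TestScramble:
    def test_preserves_counts_and_range(self, tiny_drc):
        rng = np.random.default_rng(8)
        spikes = np.sort(rng.uniform(0, tiny_drc.total_duration, 300))
        scr = R.scramble_spikes(spikes, tiny_drc, rng)
        assert scr.size == spikes.size
        assert scr.min() >= 0 and scr.max() <= tiny_drc.total_duration
        assert not np.allclose(scr, spikes)

    def test_determinism(self, tiny_drc):
        spikes = np.linspace(0.1, 19.9, 100)
        a = R.scramble_spikes(spikes, tiny_drc, np.random.default_rng(1))
        b = R.scramble_spikes(spikes, tiny_drc, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestSignificance:
    def test_planted_lobe_flagged_null_not(self, drc_grid):
        drc = X.make_drc(drc_grid, total_dur=300.0, n_files=2, seed=9)
        shape = S.make_gaussian_strf(20, 50, 8, 25)
        amp = S._strf_amplitude_for_sd(shape, 20.0, 4, 12.0)
        units = [
            S.GroundTruthUnit(unit_id="planted", spont_rate=12.0, strf_true=shape * amp),
            S.GroundTruthUnit(unit_id="null", spont_rate=12.0,
                              strf_true=np.zeros((20, 50))),
        ]
        rec = S.simulate_drc_session(units, drc, seed=10)
        design = R.STRFDesign(drc)
        est, sig = R.strf_significance(rec.units["planted"], design, "laser_off",
                                       n_reps=12, seed=11)
        lobes = R.extract_lobes(est, sig)
        assert any(l.sign == "positive" and (8, 25) in l.pixels for l in lobes)
        _, sig0 = R.strf_significance(rec.units["null"], design, "laser_off",
                                      n_reps=12, seed=12)
        assert sig0.mask.sum() == 0

        # persistence monotonicity: stricter threshold => subset mask
        strict = sig.at_threshold(sig.n_reps)
        assert np.all(~strict | sig.mask)

    def test_too_few_spikes_rejected(self, tiny_drc):
        design = R.STRFDesign(tiny_drc)
        with pytest.raises(AnalysisError):
            R.strf_significance(np.linspace(1, 19, 10), design)


def _rect_strf(pixels, sign=+1.0, n_lags=20, n_freqs=50):
    vals = np.zeros((n_lags, n_freqs))
    mask = np.zeros((n_lags, n_freqs), dtype=bool)
    for (l, f) in pixels:
        vals[l, f] = sign * 1.0
        mask[l, f] = True
    grid = X.make_frequency_grid(n_freqs, 5000.0, 40000.0)
    strf = R.STRFMatrix(values=vals, lag_bin=0.005,
                        lags=(np.arange(n_lags) + 1) * 0.005,
                        freqs=grid, condition="laser_off", n_spikes=1000)
    return strf, mask


class TestLobes:
    def test_rectangle_geometry(self):
        pixels = [(l, f) for l in range(4, 8) for f in range(10, 13)]
        strf, mask = _rect_strf(pixels)
        lobes = R.extract_lobes(strf, mask)
        assert len(lobes) == 1
        lb = lobes[0]
        assert lb.size == 12 and lb.sign == "positive"
        assert lb.temporal_width == pytest.approx(4 * 0.005)
        assert lb.frequency_width == pytest.approx(3 * strf.freqs.step_octaves)

    def test_diagonal_touching_is_one_lobe(self):
        strf, mask = _rect_strf([(3, 3), (4, 4)])
        assert len(R.extract_lobes(strf, mask)) == 1

    def test_signs_split_lobes(self):
        vals = np.zeros((20, 50))
        vals[2, 2], vals[2, 3] = 1.0, -1.0
        strf, _ = _rect_strf([])
        strf.values = vals
        mask = vals != 0
        lobes = R.extract_lobes(strf, mask)
        assert {l.sign for l in lobes} == {"positive", "negative"}

    def test_empty_mask(self):
        strf, _ = _rect_strf([(1, 1)])
        assert R.extract_lobes(strf, np.zeros_like(strf.values, dtype=bool)) == []


class TestLobeMatching:
    def _lobe(self, pixels, sign="positive"):
        return R.Lobe(sign=sign, pixels=frozenset(pixels), peak_time=0.02,
                      temporal_width=0.01, peak_frequency=10000.0,
                      frequency_width=0.2, size=len(pixels))

    def test_identical_sets_full_persistence(self):
        lobes = [self._lobe({(1, 1), (1, 2)}), self._lobe({(5, 5)}, "negative")]
        res = R.match_lobes(lobes, lobes)
        assert len(res.pairs) == 2
        assert res.persistence == {"positive": 1.0, "negative": 1.0}

    def test_disjoint_sets_zero_persistence(self):
        res = R.match_lobes([self._lobe({(1, 1)})], [self._lobe({(9, 9)})])
        assert res.pairs == []
        assert res.persistence["positive"] == 0.0

    def test_exact_half_overlap_matches(self):
        """Overlap of exactly 50% of the smaller lobe is a match (inclusive)."""
        small = self._lobe({(1, 1), (1, 2), (1, 3), (1, 4)})
        big = self._lobe({(1, 3), (1, 4), (1, 5), (1, 6), (1, 7), (1, 8)})
        res = R.match_lobes([small], [big])
        assert len(res.pairs) == 1

    def test_just_under_half_no_match(self):
        small = self._lobe({(1, 1), (1, 2), (1, 3), (1, 4), (1, 5)})
        big = self._lobe({(1, 4), (1, 5), (1, 6), (1, 7), (1, 8), (1, 9)})
        res = R.match_lobes([small], [big])  # 2/5 overlap
        assert res.pairs == []

    def test_sign_mismatch_never_matches(self):
        res = R.match_lobes([self._lobe({(1, 1)})],
                            [self._lobe({(1, 1)}, "negative")])
        assert res.pairs == []


class TestLobeComparison:
    def test_identical_strfs_zero_differences(self):
        pixels = [(l, f) for l in range(3, 6) for f in range(7, 9)]
        strf, mask = _rect_strf(pixels)
        lobes = R.extract_lobes(strf, mask)
        res = R.match_lobes(lobes, lobes)
        table = R.compare_lobe_parameters(res)
        assert len(table) == 1
        for p in ("peak_time", "temporal_width", "peak_frequency",
                  "frequency_width", "size"):
            assert (table[f"{p}_on"] == table[f"{p}_off"]).all()

    def test_empty_matches_empty_table(self):
        res = R.match_lobes([], [])
        assert R.compare_lobe_parameters(res).empty


class TestRateSplit:
    def test_modulated_unit_classified(self, drc_grid):
        drc = X.make_drc(drc_grid, total_dur=120.0, n_files=2, seed=13)
        mod = S.ModulationModel(spont_delta=8.0)
        u = S.GroundTruthUnit(unit_id="u", spont_rate=10.0,
                              strf_true=np.zeros((20, 50)), modulation=mod)
        rec = S.simulate_drc_session([u], drc, seed=14)
        out = R.drc_rate_split(rec.units["u"], drc)
        assert out["classification"] == "increased"
        assert out["delta"] == pytest.approx(8.0, abs=3.0)
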