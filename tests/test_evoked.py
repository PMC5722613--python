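import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmsep import evoked, synthgen
from tmsep.evoked import BinnedTrials, PhasicEvent, SignificanceBand
from tmsep.sigio import SpikeTrain, StimulusLog


def _stim(n=3, intensity=120.0, animal="rat0"):
    return StimulusLog(onsets=0.6 + 2.0 * np.arange(n),
                       intensity_pct_mt=intensity, animal_id=animal)


class TestBinAndNormalize:
    def test_empty_train_all_zero(self):
        bt = evoked.bin_and_normalize(SpikeTrain(np.array([])), _stim())
        assert np.all(bt.matrix == 0)
        assert bt.n_bins == 1500

    def test_baseline_mean_exactly_zero_per_trial(self):
        rng = np.random.default_rng(0)
        spikes = SpikeTrain(rng.uniform(0, 7, 800))
        bt = evoked.bin_and_normalize(spikes, _stim())
        base = bt.matrix[:, bt.baseline_bin_mask()]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-9)

    def test_three_spikes_in_one_bin(self):
        # 3 spikes inside one 1 ms bin, empty baseline -> 3000 events/s
        onset = 0.6
        spikes = SpikeTrain(np.array([onset + 0.0101, onset + 0.0105, onset + 0.0108]))
        bt = evoked.bin_and_normalize(spikes, _stim(n=1))
        i = int((10.0 - bt.window_ms[0]) / bt.bin_size_ms)
        assert bt.matrix[0, i] == pytest.approx(3000.0)
        rest = np.delete(bt.matrix[0], i)
        np.testing.assert_allclose(rest, 0.0)

    def test_overrunning_trial_dropped_with_warning(self):
        stim = _stim(n=3)
        with pytest.warns(UserWarning, match="dropped 1 trial"):
            bt = evoked.bin_and_normalize(SpikeTrain(np.array([])), stim,
                                          t_max=stim.onsets[-1] + 0.5)
        assert bt.n_trials == 2

    def test_half_open_bins_no_double_count(self):
        onset = 0.6
        spikes = SpikeTrain(np.array([onset + 0.010]))  # exactly on a bin edge
        bt = evoked.bin_and_normalize(spikes, _stim(n=1))
        assert bt.matrix.sum() == pytest.approx(1000.0, abs=1e-6)


class TestAverageTrials:
    def _bt(self, matrix, animals):
        meta = pd.DataFrame({"trial": range(len(matrix)), "intensity": 120.0,
                             "orientation": "ML", "animal": animals})
        return BinnedTrials(np.asarray(matrix, float), 1.0, (-500.0, 1000.0),
                            (-500.0, 0.0), meta)

    def test_identical_trials_average_is_any_trial(self):
        m = np.tile(np.arange(4.0), (3, 1))
        out = evoked.average_trials(self._bt(m, ["a"] * 3))
        np.testing.assert_array_equal(out["train"].iloc[0], m[0])

    def test_symmetric_trials_cancel(self):
        m = np.array([[1.0, -2.0], [-1.0, 2.0]])
        out = evoked.average_trials(self._bt(m, ["a", "a"]))
        np.testing.assert_allclose(out["train"].iloc[0], 0.0)

    def test_population_average_weights_animals_equally(self):
        # animal a: 3 trials of value 0; animal b: 1 trial of value 4
        m = np.array([[0.0], [0.0], [0.0], [4.0]])
        out = evoked.average_trials(self._bt(m, ["a", "a", "a", "b"]))
        # mean of per-animal means (0 and 4) -> 2, not the trial mean 1
        assert out["train"].iloc[0][0] == pytest.approx(2.0)

    def test_group_by_intensity(self):
        m = np.array([[1.0], [3.0], [10.0]])
        meta = pd.DataFrame({"trial": [0, 1, 2], "intensity": [95.0, 95.0, 120.0],
                             "orientation": "ML", "animal": "a"})
        bt = BinnedTrials(m, 1.0, (-500.0, 1000.0), (-500.0, 0.0), meta)
        out = evoked.average_trials(bt, group_by=["intensity"])
        got = {row["intensity"]: row["train"][0] for _, row in out.iterrows()}
        assert got == {95.0: 2.0, 120.0: 10.0}


class TestSignificanceBand:
    def test_quantiles_match_order_statistic_oracle(self):
        # independent oracle: interpolate order statistics at p*(n+1)
        values = np.arange(1.0, 101.0)
        band = evoked.significance_band(values, 100)

        def oracle(p):
            h = p * 101.0
            k = int(np.floor(h))
            srt = np.sort(values)
            return srt[k - 1] + (h - k) * (srt[k] - srt[k - 1])

        assert band.lower == pytest.approx(oracle(0.025))
        assert band.upper == pytest.approx(oracle(0.975))
        assert band.lower == pytest.approx(2.525)
        assert band.upper == pytest.approx(98.475)

    def test_constant_baseline_collapses_band(self):
        band = evoked.significance_band(np.zeros(500), 500)
        assert band.lower == band.upper == 0.0

    def test_few_baseline_bins_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            evoked.significance_band(np.arange(30.0), 30)

    def test_no_baseline_bins_is_error(self):
        with pytest.raises(ValueError):
            evoked.significance_band(np.arange(10.0), 0)


class TestSmooth:
    def test_constant_train_unchanged(self):
        x = np.full(300, 7.5)
        np.testing.assert_allclose(evoked.smooth(x), x)

    def test_impulse_mass_preserved(self):
        x = np.zeros(401)
        x[200] = 1.0
        y = evoked.smooth(x, sigma_ms=2.0, bin_size_ms=1.0)
        assert y.sum() == pytest.approx(1.0, rel=1e-6)
        assert np.argmax(y) == 200

    def test_square_bump_matches_direct_convolution(self):
        x = np.zeros(400)
        x[100:115] = 10.0  # 15 ms square bump
        y = evoked.smooth(x, sigma_ms=2.0, bin_size_ms=1.0)
        # direct convolution oracle with reflective padding
        r = 8  # 4 sigma in bins
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / 2.0) ** 2)
        k /= k.sum()
        xp = np.concatenate([x[r - 1::-1], x, x[:-r - 1:-1]])
        want = np.convolve(xp, k, mode="valid")
        np.testing.assert_allclose(y, want, atol=1e-12)
        assert abs(np.argmax(y) - 107) <= 1  # peak position unchanged


def brute_force_phasic(train, lower, upper, bin_ms, t0, min_dur, max_gap):
    """Run-length oracle: plain scans, grouping, merging, duration filter."""
    out = []
    for sign, beyond in (("excitation", train > upper), ("inhibition", train < lower)):
        idx = [i for i in range(len(train)) if beyond[i] and t0 + i * bin_ms >= 0]
        runs = []
        for i in idx:
            if runs and i == runs[-1][1] + 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        merged = []
        for a, b in runs:
            if merged and (a - merged[-1][1] - 1) * bin_ms <= max_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            if (b + 1 - a) * bin_ms > min_dur:
                out.append((sign, t0 + a * bin_ms, t0 + (b + 1) * bin_ms))
    return sorted(out, key=lambda e: e[1])


class TestDetectPhasic:
    band = SignificanceBand(lower=-1.0, upper=1.0, n_baseline_samples=500)

    def _detect(self, train, **kw):
        kw.setdefault("bin_size_ms", 1.0)
        kw.setdefault("window_ms", (0.0, float(len(train))))
        return evoked.detect_phasic(np.asarray(train, float), self.band, **kw)

    def test_never_beyond_band_no_events(self):
        assert self._detect(np.zeros(100)) == []

    def test_continuous_run_edges(self):
        train = np.zeros(100)
        train[20:35] = 5.0  # 15 ms supra-threshold
        evs = self._detect(train)
        assert len(evs) == 1
        e = evs[0]
        assert (e.polarity, e.onset_ms, e.offset_ms) == ("excitation", 20.0, 35.0)
        assert e.peak_normalized_fr == 5.0

    @pytest.mark.parametrize("gap,expected_events", [(8, 1), (12, 0)])
    def test_gap_merge_rule(self, gap, expected_events):
        train = np.zeros(100)
        train[10:18] = 5.0
        train[18 + gap:26 + gap] = 5.0
        evs = self._detect(train)
        assert len(evs) == expected_events
        if expected_events:
            assert evs[0].offset_ms - evs[0].onset_ms == 16 + gap

    def test_matches_run_length_oracle_on_random_trains(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            train = rng.normal(0, 1.2, 120)
            evs = self._detect(train)
            want = brute_force_phasic(train, -1.0, 1.0, 1.0, 0.0, 10.0, 10.0)
            got = [(e.polarity, e.onset_ms, e.offset_ms) for e in evs]
            assert got == want

    def test_inhibition_detected_independently(self):
        train = np.zeros(100)
        train[40:60] = -5.0
        evs = self._detect(train)
        assert [e.polarity for e in evs] == ["inhibition"]

    def test_nonpositive_min_dur_rejected(self):
        with pytest.raises(ValueError):
            self._detect(np.zeros(50), min_dur_ms=0.0)

    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(-50.0, 50.0))
    def test_invariant_to_constant_shift(self, shift):
        rng = np.random.default_rng(8)
        train = rng.normal(0, 1.5, 150)
        base = self._detect(train)
        band2 = SignificanceBand(self.band.lower + shift, self.band.upper + shift, 500)
        shifted = evoked.detect_phasic(train + shift, band2, bin_size_ms=1.0,
                                       window_ms=(0.0, 150.0))
        assert [(e.polarity, e.onset_ms, e.offset_ms) for e in base] == \
               [(e.polarity, e.onset_ms, e.offset_ms) for e in shifted]


class TestClassifyPhases:
    def test_canonical_three_phase_sequence(self):
        evs = [
            PhasicEvent("excitation", 8.0, 32.0, 70.0, 20.0),
            PhasicEvent("inhibition", 50.0, 150.0, -14.0, 80.0),
            PhasicEvent("excitation", 180.0, 250.0, 30.0, 210.0),
        ]
        labels = [e.label for e in evoked.classify_phases(evs)]
        assert labels == ["intermediate_excitation", "inhibition", "rebound_excitation"]

    def test_single_early_excitation_is_short_latency(self):
        evs = [PhasicEvent("excitation", 1.0, 5.0, 300.0, 3.0)]
        assert evoked.classify_phases(evs)[0].label == "short_latency"

    def test_empty_input_empty_output(self):
        assert evoked.classify_phases([]) == []

    def test_extra_events_stay_unclassified(self):
        evs = [
            PhasicEvent("excitation", 8.0, 32.0, 70.0, 20.0),
            PhasicEvent("excitation", 35.0, 48.0, 20.0, 40.0),  # second excitation, no inhibition yet
        ]
        labels = [e.label for e in evoked.classify_phases(evs)]
        assert labels == ["intermediate_excitation", "unclassified"]


class TestExtractPhaseFr:
    def test_hand_built_toy_matrix(self):
        matrix = np.array([
            [0.0, 1.0, 2.0, 3.0],
            [4.0, 5.0, 6.0, 7.0],
            [8.0, 9.0, 10.0, 11.0],
        ])
        meta = pd.DataFrame({"trial": [0, 1, 2], "intensity": 120.0,
                             "orientation": "ML", "animal": "a"})
        bt = BinnedTrials(matrix, 1.0, (0.0, 4.0), (0.0, 0.0), meta)
        ev = PhasicEvent("excitation", 1.0, 3.0, 0.0, 2.0, "intermediate_excitation")
        table = evoked.extract_phase_fr(bt, [ev])
        np.testing.assert_allclose(table["mean_fr"], [1.5, 5.5, 9.5])

    def test_zero_trials_give_zero(self):
        meta = pd.DataFrame({"trial": [0], "intensity": 120.0,
                             "orientation": "ML", "animal": "a"})
        bt = BinnedTrials(np.zeros((1, 10)), 1.0, (0.0, 10.0), (0.0, 0.0), meta)
        ev = PhasicEvent("excitation", 2.0, 6.0, 0.0, 3.0, "inhibition")
        assert evoked.extract_phase_fr(bt, [ev])["mean_fr"].iloc[0] == 0.0

    def test_single_bin_phase_returns_bin_value(self):
        meta = pd.DataFrame({"trial": [0], "intensity": 120.0,
                             "orientation": "ML", "animal": "a"})
        bt = BinnedTrials(np.array([[1.0, 7.0, 3.0]]), 1.0, (0.0, 3.0), (0.0, 0.0), meta)
        ev = PhasicEvent("excitation", 1.0, 2.0, 7.0, 1.5, "short_latency")
        assert evoked.extract_phase_fr(bt, [ev])["mean_fr"].iloc[0] == 7.0

    def test_unclassified_events_skipped(self):
        meta = pd.DataFrame({"trial": [0], "intensity": 120.0,
                             "orientation": "ML", "animal": "a"})
        bt = BinnedTrials(np.ones((1, 5)), 1.0, (0.0, 5.0), (0.0, 0.0), meta)
        ev = PhasicEvent("excitation", 0.0, 5.0, 1.0, 2.0, "unclassified")
        assert evoked.extract_phase_fr(bt, [ev]).empty
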