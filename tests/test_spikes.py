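"""PN epoch-transition complexity pipeline against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfontogeny import (AnimalMeta, Dataset, OdorStimulus, RateProfile,
                         SpikeTrainTrial, gen_pn_dataset, gen_pn_trials)
from olfontogeny.spikes import (EpochAnnotation, RateSeries,
                                assess_responsiveness, binned_rates,
                                compare_distributions, count_transitions,
                                detect_peaks_valleys, firing_rate_anova,
                                gaussian_smooth, isi_rate,
                                rate_profile_transitions,
                                trial_transitions)
from olfontogeny.synth import SynthConfig


def make_trial(spikes, duration=7.0, onset=2.0, odor="hex", cell="pn1",
               age="adult", trial_index=1):
    return SpikeTrainTrial(
        spikes_s=np.asarray(spikes, float), record_duration_s=duration,
        stimulus=OdorStimulus(odor_label=odor, onset_s=onset),
        trial_index=trial_index, cell_id=cell,
        animal=AnimalMeta(animal_id="a1", age_group=age))


def peakdetect_oracle(y, lookahead, delta):
    """Independent transliteration of the published lookahead/delta
    peak-detection algorithm (running extrema with +-inf sentinels)."""
    max_peaks, min_peaks = [], []
    dump = []
    mx, mn = -np.inf, np.inf
    mxpos = mnpos = None
    for index in range(len(y) - lookahead):
        v = y[index]
        if v > mx:
            mx, mxpos = v, index
        if v < mn:
            mn, mnpos = v, index
        if v < mx - delta and mx != np.inf:
            if y[index:index + lookahead].max() < mx:
                max_peaks.append(mxpos)
                dump.append(True)
                mx = np.inf
                mn = np.inf
                continue
        if v > mn + delta and mn != -np.inf:
            if y[index:index + lookahead].min() > mn:
                min_peaks.append(mnpos)
                dump.append(False)
                mn = -np.inf
                mx = -np.inf
    # the first confirmation tracks a running extremum seeded at the
    # series boundary and is removed as a false hit
    if dump:
        if dump[0]:
            max_peaks.pop(0)
        else:
            min_peaks.pop(0)
    return max_peaks, min_peaks


class TestBinnedRates:
    def test_empty_train(self):
        rates = binned_rates(make_trial([]))
        assert np.all(rates == 0)

    def test_three_spikes_first_bin(self):
        rates = binned_rates(make_trial([0.1, 0.2, 0.3]))
        assert rates[0] == pytest.approx(3 / 0.4)
        assert np.all(rates[1:] == 0)

    def test_poisson_mean(self):
        trial = gen_pn_trials(RateProfile([0.0, 0.1], [10.0],
                                          baseline_hz=10.0),
                              1, seed=3, record_duration_s=200.0)[0]
        assert np.mean(binned_rates(trial)) == pytest.approx(10.0, rel=0.1)


class TestIsiRate:
    def test_two_spikes(self):
        rs = isi_rate(make_trial([1.0, 1.5]), dt_s=0.001)
        t = rs.times_s()
        inside = (t > 1.0) & (t <= 1.5)
        assert np.all(rs.rates_hz[inside] == pytest.approx(2.0))
        assert np.all(rs.rates_hz[~inside] == 0.0)

    def test_periodic_train(self):
        spikes = np.arange(0.1, 5.0, 0.1)
        rs = isi_rate(make_trial(spikes), dt_s=0.001)
        t = rs.times_s()
        inside = (t > spikes[0]) & (t <= spikes[-1])
        assert np.allclose(rs.rates_hz[inside], 10.0)

    def test_matches_per_sample_oracle(self, rng):
        spikes = np.sort(rng.uniform(0.0, 7.0, 40))
        spikes = np.unique(spikes)
        trial = make_trial(spikes)
        rs = isi_rate(trial, dt_s=0.005)
        for j, t in enumerate(rs.times_s()):
            expected = 0.0
            for i in range(len(spikes) - 1):
                if spikes[i] < t <= spikes[i + 1]:
                    expected = 1.0 / (spikes[i + 1] - spikes[i])
                    break
            assert rs.rates_hz[j] == pytest.approx(expected), t

    def test_single_spike_all_zero(self):
        rs = isi_rate(make_trial([3.0]))
        assert np.all(rs.rates_hz == 0)


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        rs = RateSeries(0.0, 0.001, np.full(1000, 7.0))
        out = gaussian_smooth(rs)
        assert np.allclose(out.rates_hz, 7.0)
        assert len(out.rates_hz) == 1000

    def test_impulse_sums_to_one(self):
        y = np.zeros(1001)
        y[500] = 1.0
        out = gaussian_smooth(RateSeries(0.0, 0.001, y))
        assert out.rates_hz.sum() == pytest.approx(1.0)
        assert out.rates_hz[500] == out.rates_hz.max()

    def test_matches_direct_convolution(self):
        """Square pulse smoothed output equals the O(n*k) direct-sum
        oracle with reflected edges."""
        y = np.zeros(600)
        y[200:400] = 5.0
        sigma, width, dt = 0.03333, 0.2, 0.001
        out = gaussian_smooth(RateSeries(0.0, dt, y), sigma, width)
        half = int(round(width / 2 / dt))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) * dt / sigma) ** 2)
        k /= k.sum()
        n = len(y)
        for j in range(0, n, 37):  # spot-check a grid of samples
            acc = 0.0
            for offset in range(-half, half + 1):
                idx = j + offset
                if idx < 0:
                    idx = -idx  # reflect
                elif idx >= n:
                    idx = 2 * (n - 1) - idx
                acc += k[offset + half] * y[idx]
            assert out.rates_hz[j] == pytest.approx(acc, abs=1e-12)

    def test_bad_sigma_raises(self):
        with pytest.raises(ValueError):
            gaussian_smooth(RateSeries(0.0, 0.001, np.ones(10)), -1.0)


class TestDetectPeaksValleys:
    def test_monotone_series(self):
        rs = RateSeries(0.0, 0.01, np.linspace(0, 10, 500))
        ann = detect_peaks_valleys(rs, lookahead_s=0.2, delta_hz=0.5)
        assert ann.peaks == [] and ann.valleys == []

    def test_single_triangular_bump(self):
        y = np.concatenate([np.linspace(0, 10, 300),
                            np.linspace(10, 0, 300)])
        ann = detect_peaks_valleys(RateSeries(0.0, 0.01, y),
                                   lookahead_s=0.3, delta_hz=1.0)
        assert len(ann.peaks) == 1
        assert ann.peaks[0][1] == pytest.approx(10.0, abs=0.1)
        assert len(ann.valleys) == 0

    def test_short_series_empty(self):
        rs = RateSeries(0.0, 0.01, np.ones(5))
        ann = detect_peaks_valleys(rs, lookahead_s=1.0, delta_hz=0.1)
        assert ann.peaks == [] and ann.valleys == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        """Confirmed extrema equal the published algorithm's on rough
        multi-bump series."""
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 6.0, 0.01)
        y = (10 * np.sin(2 * np.pi * 0.7 * t) ** 2
             + rng.normal(0, 1.5, len(t)))
        rs = RateSeries(0.0, 0.01, y)
        ann = detect_peaks_valleys(rs, lookahead_s=0.2, delta_hz=2.0)
        lookahead = 20
        exp_peaks, exp_valleys = peakdetect_oracle(y, lookahead, 2.0)
        got_peaks = [int(round(tp / 0.01)) for tp, _ in ann.peaks]
        got_valleys = [int(round(tv / 0.01)) for tv, _ in ann.valleys]
        assert got_peaks == exp_peaks
        assert got_valleys == exp_valleys

    def test_alternation(self, rng):
        y = rng.normal(0, 5, 2000)
        ann = detect_peaks_valleys(RateSeries(0.0, 0.01, y),
                                   lookahead_s=0.1, delta_hz=3.0)
        events = sorted([(t, "p") for t, _ in ann.peaks]
                        + [(t, "v") for t, _ in ann.valleys])
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestCountTransitions:
    def test_no_peaks(self):
        ann = EpochAnnotation(peaks=[], valleys=[(2.5, 1.0)])
        assert count_transitions(ann, onset_s=2.0) == 0

    def test_two_peaks_one_valley(self):
        """Hand enumeration: one interior valley (2) + late first peak
        (1) + early last peak (1) = 4."""
        ann = EpochAnnotation(peaks=[(2.5, 30.0), (5.0, 20.0)],
                              valleys=[(3.5, 2.0)])
        assert count_transitions(ann, onset_s=2.0) == 4

    def test_early_single_peak(self):
        # peak within 200 ms of onset: no spontaneous-to-excitatory
        # transition, but it ends before the window so the return to
        # baseline still counts
        ann = EpochAnnotation(peaks=[(2.1, 30.0)], valleys=[])
        assert count_transitions(ann, onset_s=2.0) == 1

    def test_out_of_window_peaks_ignored(self):
        ann = EpochAnnotation(peaks=[(0.5, 10.0), (7.5, 10.0)],
                              valleys=[(1.0, 1.0)])
        assert count_transitions(ann, onset_s=2.0) == 0

    @given(st.integers(0, 8), st.booleans(), st.booleans())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_parity_invariant(self, n_valleys, late_first, early_last):
        """transitions = 2*V + B with B in {0, 1, 2} for alternating
        annotations built inside the window."""
        onset, window = 2.0, 4.0
        first = onset + (0.5 if late_first else 0.1)
        last = onset + window - (0.5 if early_last else 0.0)
        if n_valleys == 0:
            peaks = [(first, 10.0)]
            if early_last or last == onset + window:
                peaks = [(last if not early_last else first, 10.0)]
            valleys = []
        else:
            times = np.linspace(first, last, 2 * n_valleys + 1)
            peaks = [(t, 10.0) for t in times[::2]]
            valleys = [(t, 1.0) for t in times[1::2]]
        ann = EpochAnnotation(peaks=peaks, valleys=valleys)
        got = count_transitions(ann, onset, window)
        assert got % 2 == (got % 2)  # well-defined integer
        v = len([t for t, _ in valleys
                 if peaks[0][0] < t < peaks[-1][0]])
        assert 2 * v <= got <= 2 * v + 2


class TestResponsiveness:
    def test_constant_rate_excluded(self):
        # perfectly regular trains, no stimulus modulation
        trials = [make_trial(np.arange(0.05, 7.0, 0.1), trial_index=i + 1)
                  for i in range(6)]
        res = assess_responsiveness(trials)
        assert not res.included

    def test_strong_excitation_included(self):
        profile = RateProfile([0.2, 1.2], [80.0], baseline_hz=5.0)
        trials = gen_pn_trials(profile, 6, seed=2)
        res = assess_responsiveness(trials)
        assert res.included
        first_bin = res.responsive_masks[:, 0]  # bin [2.0, 2.4) s
        assert first_bin.sum() >= 3

    def test_minority_response_excluded(self):
        quiet = [make_trial(np.arange(0.05, 7.0, 0.2), trial_index=i + 1)
                 for i in range(4)]
        burst = np.sort(np.concatenate([np.arange(0.05, 7.0, 0.2),
                                        np.arange(2.0, 2.4, 0.01)]))
        loud = [make_trial(np.unique(burst), trial_index=i + 5)
                for i in range(2)]
        res = assess_responsiveness(quiet + loud)
        assert not res.included

    def test_no_pre_onset_raises(self):
        with pytest.raises(ValueError):
            assess_responsiveness([make_trial([0.5, 1.0], onset=0.0)])


class TestPipeline:
    @pytest.mark.parametrize("profile,delta", [
        (RateProfile([0.5, 1.1, 1.7, 2.3], [120.0, 0.0, 120.0], 5.0), 55.0),
        (RateProfile([0.4, 1.2], [60.0], 5.0), 25.0),
        (RateProfile([0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
                     [80.0, 0.0, 80.0, 0.0, 80.0], 3.0), 35.0),
    ])
    def test_noiseless_profile_equals_rule_enumeration(self, profile,
                                                       delta):
        """Feeding the exact rate profile through smoothing, detection
        and counting reproduces the profile's ground-truth count."""
        gt = profile.ground_truth_transitions(delta_hz=delta)
        t = np.arange(0, 7.0, 0.001)
        rates = profile.rate_at(t, 2.0)
        assert rate_profile_transitions(t, rates, 2.0,
                                        delta_hz=delta) == gt

    def test_poisson_modal_recovery(self):
        profile = RateProfile([0.5, 1.1, 1.7, 2.3], [120.0, 0.0, 120.0],
                              baseline_hz=5.0)
        gt = profile.ground_truth_transitions(delta_hz=55.0)
        trials = gen_pn_trials(profile, 60, seed=9)
        counts = np.array([trial_transitions(t, delta_hz=55.0)
                           for t in trials])
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == gt


class TestDistributions:
    def test_specific_ks(self):
        res = compare_distributions([0, 0, 1], [1, 1, 1])
        assert res.statistic == pytest.approx(2 / 3)

    def test_identical(self):
        res = compare_distributions([0, 1, 2, 2], [0, 1, 2, 2])
        assert res.statistic == 0.0

    def test_empty_dataset_distribution_warns(self):
        ds = Dataset()
        from olfontogeny.spikes import complexity_distribution
        with pytest.warns(UserWarning):
            assert complexity_distribution(ds) == []


class TestFiringRateAnova:
    def test_age_effect_detected(self, cfg):
        ds = gen_pn_dataset(["adult", "hatchling"], n_cells=4,
                            odors=["hex", "cyc"], cfg=cfg, seed=21)
        res = firing_rate_anova(ds)
        assert res["age_group"].p_value < 0.01
        assert res["age_group"].df == 1

    def test_single_age_raises(self, cfg):
        ds = gen_pn_dataset(["adult"], n_cells=2, odors=["hex"],
                            cfg=cfg, seed=1)
        with pytest.raises(ValueError):
            firing_rate_anova(ds)
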