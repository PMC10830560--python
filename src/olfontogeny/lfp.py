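"""Odor-evoked LFP oscillation analysis.

Odor pulses elicit ~20 Hz oscillations in the mushroom-body LFP of
adult locusts, reflecting synchronized projection-neuron populations.
The pipeline: zero-phase band-pass 3-50 Hz, short-time spectrograms
(0.5 s Hann window, 50% overlap, hence 2 Hz frequency resolution),
averaging of trials 3-10 (oscillations usually develop only after two
odor presentations), and extraction of the frequency with peak power
within 1 s after odor onset. Oscillation amplitude, duration and onset
latency are measured from the analytic-signal envelope of the
band-passed trial average.

The antennal-trimming analysis regresses the per-stage peak frequency
on the number of antennal segments cut; the contralateral (untrimmed)
side serves as a within-animal control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
import statsmodels.api as sm

from .datamodel import AnalogTrial, Dataset, OdorStimulus

BAND_LOW_HZ = 3.0
BAND_HIGH_HZ = 50.0
WINDOW_S = 0.5
OVERLAP_FRACTION = 0.5
TRIAL_RANGE = (3, 10)


@dataclass
class SpectrogramResult:
    """Short-time power spectrum; ``power`` has shape
    (n_freq, n_time)."""

    time_centers_s: np.ndarray
    freq_centers_hz: np.ndarray
    power: np.ndarray
    window_s: float = WINDOW_S
    overlap_fraction: float = OVERLAP_FRACTION


@dataclass
class PeakFrequencyResult:
    frequency_hz: float
    power: float
    low_confidence: bool

    def __float__(self) -> float:
        return self.frequency_hz


@dataclass
class OscillationSummary:
    peak_frequency_hz: float
    amplitude_mV: float
    duration_s: float
    latency_s: Optional[float]
    low_confidence: bool = False


@dataclass
class TrimRegressionResult:
    side: str
    slope_hz_per_cut: float
    slope_se: float
    r2: float
    p_value: float
    n_points: int
    intercept_hz: float


def bandpass_3_50(trial: AnalogTrial) -> AnalogTrial:
    """Zero-phase 4th-order Butterworth band-pass, 3-50 Hz.

    Forward-backward filtering preserves the timing of oscillation
    onsets, which the latency estimates depend on. The DC component is
    fully removed by the band-pass.
    """
    if trial.fs_hz <= 2 * BAND_HIGH_HZ:
        raise ValueError(f"fs_hz = {trial.fs_hz} too low for a "
                         f"{BAND_HIGH_HZ} Hz band edge")
    sos = signal.butter(4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass",
                        fs=trial.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trial.values_mV)
    return AnalogTrial(values_mV=filtered, fs_hz=trial.fs_hz,
                       modality=trial.modality, stimulus=trial.stimulus,
                       trial_index=trial.trial_index, side=trial.side,
                       animal=trial.animal, meta=dict(trial.meta))


def compute_spectrogram(trial: AnalogTrial,
                        window_s: float = WINDOW_S,
                        overlap_fraction: float = OVERLAP_FRACTION
                        ) -> SpectrogramResult:
    """Hann-tapered short-time power spectrum.

    With the 0.5 s default window the frequency resolution is 2 Hz
    (no zero-padding); the hop is 0.25 s and time centers sit at the
    window midpoints.
    """
    nperseg = int(np.round(window_s * trial.fs_hz))
    if len(trial.values_mV) < nperseg:
        raise ValueError("trace shorter than one spectrogram window")
    noverlap = int(np.round(nperseg * overlap_fraction))
    freqs, times, power = signal.spectrogram(
        trial.values_mV, fs=trial.fs_hz, window="hann",
        nperseg=nperseg, noverlap=noverlap, detrend=False,
        scaling="density", mode="psd")
    return SpectrogramResult(time_centers_s=times, freq_centers_hz=freqs,
                             power=power, window_s=window_s,
                             overlap_fraction=overlap_fraction)


def average_spectrograms(trials: Sequence[AnalogTrial],
                         trial_range: Optional[Tuple[int, int]] = TRIAL_RANGE,
                         **spec_kwargs) -> SpectrogramResult:
    """Element-wise mean of per-trial spectrogram power.

    ``trial_range`` selects trials by 1-based ``trial_index``
    (inclusive); the default 3-10 excludes the first two trials, in
    which oscillations are usually still developing. Pass ``None`` to
    average every given trial.
    """
    if trial_range is not None:
        lo, hi = trial_range
        trials = [t for t in trials if lo <= t.trial_index <= hi]
    if not trials:
        raise ValueError("no trials in the requested trial range")
    specs = [compute_spectrogram(t, **spec_kwargs) for t in trials]
    shape = specs[0].power.shape
    for s in specs[1:]:
        if s.power.shape != shape:
            raise ValueError("trials have mismatched spectrogram shapes; "
                             "check sampling rates and lengths")
    mean_power = np.mean([s.power for s in specs], axis=0)
    return SpectrogramResult(time_centers_s=specs[0].time_centers_s,
                             freq_centers_hz=specs[0].freq_centers_hz,
                             power=mean_power,
                             window_s=specs[0].window_s,
                             overlap_fraction=specs[0].overlap_fraction)


def peak_frequency(spec: SpectrogramResult, stimulus: OdorStimulus,
                   window_s: float = 1.0,
                   band: Tuple[float, float] = (BAND_LOW_HZ, BAND_HIGH_HZ),
                   prominence_factor: float = 3.0,
                   absolute_window: Optional[Tuple[float, float]] = None
                   ) -> PeakFrequencyResult:
    """Frequency of the global power maximum within 1 s after odor
    onset (or an absolute-time window override), restricted to the
    analysis band.

    The result is flagged low-confidence when the peak power is below
    ``prominence_factor`` times the median power of the same frequency
    row across all time columns — i.e. when the "burst" is no stronger
    than the ongoing background at that frequency, as for pure noise.
    (A flat-spectrum guard against the in-window median would be
    fooled by 1/f-like backgrounds, whose low-frequency bins always
    dominate.)
    """
    if absolute_window is not None:
        lo_t, hi_t = absolute_window
    else:
        lo_t, hi_t = stimulus.onset_s, stimulus.onset_s + window_s
    t_mask = (spec.time_centers_s >= lo_t) & (spec.time_centers_s <= hi_t)
    f_mask = (spec.freq_centers_hz >= band[0]) & \
             (spec.freq_centers_hz <= band[1])
    if not np.any(t_mask):
        raise ValueError(f"no spectrogram columns in window "
                         f"[{lo_t}, {hi_t}] s")
    sub = spec.power[np.ix_(f_mask, t_mask)]
    fi, ti = np.unravel_index(np.argmax(sub), sub.shape)
    peak_power = float(sub[fi, ti])
    row = spec.power[np.flatnonzero(f_mask)[fi], :]
    row_median = float(np.median(row))
    low_conf = peak_power < prominence_factor * row_median \
        if row_median > 0 else peak_power <= 0
    return PeakFrequencyResult(
        frequency_hz=float(spec.freq_centers_hz[f_mask][fi]),
        power=peak_power, low_confidence=low_conf)


def oscillation_summary(trials: Sequence[AnalogTrial],
                        envelope_threshold_sd: float = 2.0,
                        envelope_floor_frac: float = 0.05,
                        peak_window_s: float = 1.0) -> OscillationSummary:
    """Frequency, amplitude, duration and onset latency of the
    odor-evoked oscillation burst.

    Frequency comes from the trial-averaged spectrogram (all given
    trials). Amplitude is the maximum of the Hilbert envelope of the
    band-passed trial average after onset; duration is the longest
    contiguous post-onset span with the envelope above the pre-onset
    mean plus ``envelope_threshold_sd`` baseline SDs, and latency is
    the first such crossing after onset. The threshold is floored at
    ``envelope_floor_frac`` of the post-onset envelope maximum so that
    a noise-free baseline (SD ~ 0) does not make every sample a
    crossing. If the envelope never crosses the threshold, duration is
    0 and latency is reported missing.
    """
    if not trials:
        raise ValueError("need at least one trial")
    filtered = [bandpass_3_50(t) for t in trials]
    spec = average_spectrograms(filtered, trial_range=None)
    stim = trials[0].stimulus
    pf = peak_frequency(spec, stim, window_s=peak_window_s)

    mean_trace = np.mean([t.values_mV for t in filtered], axis=0)
    fs = filtered[0].fs_hz
    envelope = np.abs(signal.hilbert(mean_trace))
    onset_idx = int(np.round(stim.onset_s * fs))
    baseline = envelope[:onset_idx]
    if len(baseline) < 2:
        raise ValueError("no pre-onset samples for the envelope baseline")
    post = envelope[onset_idx:]
    threshold = max(
        baseline.mean() + envelope_threshold_sd * baseline.std(),
        envelope_floor_frac * float(post.max()))
    above = post > threshold
    amplitude = float(post.max())
    if not np.any(above):
        return OscillationSummary(peak_frequency_hz=pf.frequency_hz,
                                  amplitude_mV=amplitude, duration_s=0.0,
                                  latency_s=None,
                                  low_confidence=pf.low_confidence)
    # longest contiguous run above threshold
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    longest = int(np.argmax(ends - starts))
    duration = float((ends[longest] - starts[longest]) / fs)
    latency = float(starts[0] / fs)
    return OscillationSummary(peak_frequency_hz=pf.frequency_hz,
                              amplitude_mV=amplitude, duration_s=duration,
                              latency_s=latency,
                              low_confidence=pf.low_confidence)


def stage_peak_frequencies(ds: Dataset, side: str,
                           trial_range: Tuple[int, int] = TRIAL_RANGE
                           ) -> pd.DataFrame:
    """Per-(antenna, stage) peak frequency table for a trim experiment.

    LFP trials are grouped by animal and trim stage; each group is
    band-passed, its trials 3-10 spectrogram-averaged, and the peak
    frequency extracted. Returns columns animal_id, stage, cuts,
    frequency_hz.
    """
    groups = {}
    for trial in ds.analog(modality="LFP", side=side):
        key = (trial.animal.animal_id, trial.meta.get("stage", 0))
        groups.setdefault(key, []).append(trial)
    rows = []
    for (animal_id, stage), trials in sorted(groups.items()):
        filtered = [bandpass_3_50(t) for t in trials]
        spec = average_spectrograms(filtered, trial_range=trial_range)
        pf = peak_frequency(spec, trials[0].stimulus)
        rows.append({"animal_id": animal_id, "stage": stage,
                     "cuts": trials[0].meta.get("cuts", 0),
                     "frequency_hz": pf.frequency_hz,
                     "low_confidence": pf.low_confidence})
    return pd.DataFrame(rows)


def trim_frequency_regression(ds: Dataset, side: str = "ipsi",
                              trial_range: Tuple[int, int] = TRIAL_RANGE
                              ) -> TrimRegressionResult:
    """OLS of per-stage peak LFP frequency on the number of antennal
    segments cut, for one recording side."""
    table = stage_peak_frequencies(ds, side, trial_range)
    if table.empty or table["cuts"].nunique() < 2:
        raise ValueError(f"need >= 2 distinct cut counts on side "
                         f"{side!r} for a regression")
    freqs = table["frequency_hz"].to_numpy(dtype=float)
    if np.ptp(freqs) == 0:
        # no frequency change at all (typical of an untrimmed control
        # side after bin quantization): slope is exactly 0
        return TrimRegressionResult(side=side, slope_hz_per_cut=0.0,
                                    slope_se=0.0, r2=0.0, p_value=1.0,
                                    n_points=len(freqs),
                                    intercept_hz=float(freqs[0]))
    X = sm.add_constant(table["cuts"].to_numpy(dtype=float))
    fit = sm.OLS(freqs, X).fit()
    return TrimRegressionResult(side=side,
                                slope_hz_per_cut=float(fit.params[1]),
                                slope_se=float(fit.bse[1]),
                                r2=float(fit.rsquared),
                                p_value=float(fit.pvalues[1]),
                                n_points=int(fit.nobs),
                                intercept_hz=float(fit.params[0]))
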