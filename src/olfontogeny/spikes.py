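"""Projection-neuron response-complexity analysis.

Adult locust PNs respond to odors with multiphasic sequences of
excitation and inhibition. The complexity statistic implemented here
counts transitions between these epochs in a 4 s window from odor
onset, per trial:

1. gate PN-odor pairs by responsiveness (400 ms binned rates compared
   with the pre-stimulus baseline; a pair enters only if at least half
   its trials respond in the same bin);
2. estimate the instantaneous firing rate as the inverse inter-spike
   interval (ISI), sampled on a 1 ms grid;
3. smooth with a Gaussian window (33.33 ms SD, 200 ms = 6 SD support);
4. detect alternating local peaks and valleys with a lookahead/delta
   algorithm — peaks mark excitatory epochs, the valleys between them
   inhibitory epochs;
5. count transitions: each valley between two in-window peaks counts
   twice (excitatory-to-inhibitory and back); a first peak later than
   200 ms after onset adds a spontaneous-to-excitatory transition, and
   a last peak before the window end adds an excitatory-to-baseline
   transition.

Per-age distributions of these counts are compared with a two-sample
Kolmogorov-Smirnov test; mean firing rates are compared across age and
odor with a two-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import Dataset, SpikeTrainTrial
from .stats import TestResult, anova_two_way, ks_two_sample

RESPONSE_WINDOW_S = 4.0  # counting window after odor onset
BIN_S = 0.4              # histogram bin width for responsiveness gating
EARLY_PEAK_MARGIN_S = 0.2


@dataclass
class RateSeries:
    """Uniformly sampled instantaneous firing-rate estimate."""

    t0_s: float
    dt_s: float
    rates_hz: np.ndarray

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.rates_hz)) * self.dt_s


@dataclass
class EpochAnnotation:
    """Alternating peaks (excitatory epochs) and valleys (inhibitory
    epochs) of a smoothed rate series, as (time_s, rate_hz) pairs."""

    peaks: List[Tuple[float, float]]
    valleys: List[Tuple[float, float]]
    transitions: Optional[int] = None
    window: Optional[Tuple[float, float]] = None


@dataclass
class ResponsivenessResult:
    pn_odor_id: str
    baseline_hz: float
    baseline_sd_hz: float
    responsive_masks: np.ndarray  # trials x response bins, boolean
    included: bool


def binned_rates(trial: SpikeTrainTrial, bin_s: float = BIN_S) -> np.ndarray:
    """Spike rate per bin by simple histogram: counts in
    [k*bin, (k+1)*bin) divided by the bin width."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.ceil(trial.record_duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(trial.spikes_s, bins=edges)
    return counts / bin_s


def assess_responsiveness(trials: Sequence[SpikeTrainTrial],
                          bin_s: float = BIN_S,
                          window_s: float = RESPONSE_WINDOW_S,
                          sd_mode: str = "pooled") -> ResponsivenessResult:
    """Gate one PN-odor pair by responsiveness.

    The baseline is the mean pre-stimulus binned rate averaged across
    trials. A trial is responsive in a bin if its rate there differs
    from the baseline by more than one standard deviation of the
    pre-stimulus bin rates. ``sd_mode='pooled'`` (default) takes that SD
    over pre-stimulus bins pooled across all trials of the pair;
    ``'per_trial'`` compares each trial against the SD of its own
    pre-stimulus bins. The pair is included if some response bin is
    responsive in at least half the trials.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if sd_mode not in ("pooled", "per_trial"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    onset = trials[0].stimulus.onset_s
    n_pre = int(np.floor(onset / bin_s))
    if n_pre < 1:
        raise ValueError("no pre-onset data: baseline undefined")
    n_resp = int(np.round(window_s / bin_s))
    first_resp = int(np.floor(onset / bin_s))

    pre = np.empty((len(trials), n_pre))
    resp = np.empty((len(trials), n_resp))
    for i, trial in enumerate(trials):
        rates = binned_rates(trial, bin_s)
        pre[i] = rates[:n_pre]
        padded = np.concatenate([rates, np.zeros(max(
            0, first_resp + n_resp - len(rates)))])
        resp[i] = padded[first_resp:first_resp + n_resp]

    baseline = float(np.mean(pre))
    pooled_sd = float(np.std(pre, ddof=1)) if pre.size > 1 else 0.0
    if sd_mode == "pooled":
        sd = np.full(len(trials), pooled_sd)
    else:
        sd = np.array([np.std(p, ddof=1) if len(p) > 1 else 0.0
                       for p in pre])
    masks = np.abs(resp - baseline) > sd[:, None]
    included = bool(np.any(masks.sum(axis=0) * 2 >= len(trials)))
    cell = trials[0].cell_id
    odor = trials[0].stimulus.odor_label
    return ResponsivenessResult(pn_odor_id=f"{cell}:{odor}",
                                baseline_hz=baseline,
                                baseline_sd_hz=pooled_sd,
                                responsive_masks=masks,
                                included=included)


def isi_rate(trial: SpikeTrainTrial, dt_s: float = 0.001) -> RateSeries:
    """Instantaneous firing rate as the inverse inter-spike interval.

    For t in (t_i, t_{i+1}] between consecutive spikes, the rate is
    1/(t_{i+1} - t_i); before the first and after the last spike the
    rate is zero (1/ISI is undefined there and zero matches "no
    observed activity"). Fewer than two spikes give an all-zero series.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    n = int(np.round(trial.record_duration_s / dt_s))
    t = np.arange(n) * dt_s
    rates = np.zeros(n)
    spikes = np.asarray(trial.spikes_s)
    if len(spikes) >= 2:
        idx = np.searchsorted(spikes, t, side="left")
        valid = (idx >= 1) & (idx <= len(spikes) - 1)
        iv = idx[valid]
        rates[valid] = 1.0 / (spikes[iv] - spikes[iv - 1])
    return RateSeries(t0_s=0.0, dt_s=dt_s, rates_hz=rates)


def gaussian_smooth(rs: RateSeries, sigma_s: float = 0.03333,
                    width_s: float = 0.2) -> RateSeries:
    """Convolve with a truncated, unit-sum Gaussian kernel.

    The kernel spans ``width_s`` (6 standard deviations by default).
    Edges are reflect-padded so a constant series passes through
    unchanged and no spurious edge valleys are created; output length
    equals input length.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    half = max(1, int(np.round(width_s / 2 / rs.dt_s)))
    x = np.arange(-half, half + 1) * rs.dt_s
    kernel = np.exp(-0.5 * (x / sigma_s) ** 2)
    kernel /= kernel.sum()
    y = rs.rates_hz
    if len(y) == 0:
        return RateSeries(rs.t0_s, rs.dt_s, y.copy())
    # reflect padding needs len > pad width; fall back to edge padding
    # for series shorter than the kernel half-width
    padded = np.pad(y, half, mode="reflect") if len(y) > half else \
        np.pad(y, half, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return RateSeries(rs.t0_s, rs.dt_s, smoothed)


def detect_peaks_valleys(rs: RateSeries, lookahead_s: float = 0.2,
                         delta_hz: float = 0.0) -> EpochAnnotation:
    """Lookahead/delta detection of alternating local extrema.

    The scan tracks the running candidate maximum (minimum) since the
    last confirmed extremum. A peak is confirmed at the candidate
    maximum's position when the current sample falls below candidate
    minus ``delta_hz`` and no sample within the next ``lookahead_s``
    horizon exceeds the candidate; valleys are confirmed symmetrically.
    Confirmed extrema strictly alternate, starting with whichever kind
    is confirmed first; the very first confirmation is then discarded,
    since the running extremum it tracks starts at the series boundary
    and is usually an artifact (a monotone ramp would otherwise yield
    a spurious boundary extremum). Extrema within the final lookahead
    horizon are never confirmed; a series shorter than the lookahead
    yields an empty annotation.
    """
    y = np.asarray(rs.rates_hz, dtype=float)
    lookahead = max(1, int(np.round(lookahead_s / rs.dt_s)))
    peaks: List[Tuple[float, float]] = []
    valleys: List[Tuple[float, float]] = []
    if len(y) <= lookahead:
        return EpochAnnotation(peaks=peaks, valleys=valleys)

    t = rs.times_s()
    mx, mn = -np.inf, np.inf
    mxpos = mnpos = 0
    first_kind = None  # kind of the first confirmation, to discard
    search = "either"  # then alternates 'peak' <-> 'valley'
    for i in range(len(y) - lookahead):
        v = y[i]
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn, mnpos = v, i
        if search in ("either", "peak") and v < mx - delta_hz:
            if np.max(y[i:i + lookahead]) < mx:
                peaks.append((t[mxpos], mx))
                first_kind = first_kind or "peak"
                search = "valley"
                mn = np.inf  # minimum tracking restarts after this sample
                continue
        if search in ("either", "valley") and v > mn + delta_hz:
            if np.min(y[i:i + lookahead]) > mn:
                valleys.append((t[mnpos], mn))
                first_kind = first_kind or "valley"
                search = "peak"
                mx = -np.inf  # maximum tracking restarts after this sample
    if first_kind == "peak":
        peaks.pop(0)
    elif first_kind == "valley":
        valleys.pop(0)
    return EpochAnnotation(peaks=peaks, valleys=valleys)


def count_transitions(ann: EpochAnnotation, onset_s: float,
                      window_s: float = RESPONSE_WINDOW_S) -> int:
    """Count epoch transitions inside [onset, onset + window].

    Each valley strictly between two in-window peaks counts for two
    transitions (excitatory-to-inhibitory and inhibitory-to-excitatory).
    If the first in-window peak appears more than 200 ms after odor
    onset, a spontaneous-to-excitatory transition is added; if the last
    in-window peak appears before the end of the window, an
    excitatory-to-baseline transition is added. The boundary increments
    apply to the first and last peak only, so interior epochs are not
    double-counted beyond their valleys.
    """
    end = onset_s + window_s
    peak_times = [tp for tp, _ in ann.peaks if onset_s <= tp <= end]
    if not peak_times:
        return 0
    first, last = peak_times[0], peak_times[-1]
    n_valleys = sum(1 for tv, _ in ann.valleys if first < tv < last)
    transitions = 2 * n_valleys
    if first > onset_s + EARLY_PEAK_MARGIN_S:
        transitions += 1
    if last < end:
        transitions += 1
    return transitions


def trial_transitions(trial: SpikeTrainTrial, dt_s: float = 0.001,
                      sigma_s: float = 0.03333, width_s: float = 0.2,
                      lookahead_s: float = 0.2,
                      delta_hz: Optional[float] = None,
                      window_s: float = RESPONSE_WINDOW_S) -> int:
    """Full per-trial pipeline: ISI rate, Gaussian smoothing, peak and
    valley detection, transition counting.

    When ``delta_hz`` is None the detector's prominence floor is set to
    one standard deviation of the smoothed pre-onset rate, tying it to
    the responsiveness criterion.
    """
    rs = gaussian_smooth(isi_rate(trial, dt_s), sigma_s, width_s)
    onset = trial.stimulus.onset_s
    if delta_hz is None:
        n_pre = int(np.floor(onset / rs.dt_s))
        delta_hz = float(np.std(rs.rates_hz[:n_pre])) if n_pre > 1 else 0.0
    ann = detect_peaks_valleys(rs, lookahead_s, delta_hz)
    return count_transitions(ann, onset, window_s)


def rate_profile_transitions(times_s: np.ndarray, rates_hz: np.ndarray,
                             onset_s: float, dt_s: float = 0.001,
                             sigma_s: float = 0.03333,
                             width_s: float = 0.2,
                             lookahead_s: float = 0.2,
                             delta_hz: float = 0.0,
                             window_s: float = RESPONSE_WINDOW_S) -> int:
    """Transition count of a noiseless rate profile fed straight into
    the smoothing/detection/counting chain (no spike sampling).

    This is the rule-enumeration reference used to store ground-truth
    transition counts for synthetic profiles.
    """
    rs = RateSeries(t0_s=float(times_s[0]), dt_s=dt_s,
                    rates_hz=np.asarray(rates_hz, dtype=float))
    smoothed = gaussian_smooth(rs, sigma_s, width_s)
    ann = detect_peaks_valleys(smoothed, lookahead_s, delta_hz)
    return count_transitions(ann, onset_s, window_s)


def _group_pairs(ds: Dataset, age_group: Optional[str]
                 ) -> Dict[Tuple[str, str], List[SpikeTrainTrial]]:
    pairs: Dict[Tuple[str, str], List[SpikeTrainTrial]] = {}
    for trial in ds.spike_trials:
        if age_group is not None and trial.animal.age_group != age_group:
            continue
        key = (trial.cell_id, trial.stimulus.odor_label)
        pairs.setdefault(key, []).append(trial)
    for trials in pairs.values():
        trials.sort(key=lambda tr: tr.trial_index)
    return pairs


def complexity_distribution(ds: Dataset, age_group: Optional[str] = None,
                            sd_mode: str = "pooled",
                            lookahead_s: float = 0.2,
                            delta_hz: Optional[float] = None,
                            **pipeline_kwargs) -> List[int]:
    """Per-trial transition counts over all responsive PN-odor pairs of
    one age group.

    Only pairs passing the responsiveness gate contribute; every trial
    of an included pair yields one count.
    """
    counts: List[int] = []
    for (_cell, _odor), trials in sorted(_group_pairs(ds, age_group).items()):
        gate = assess_responsiveness(trials, sd_mode=sd_mode)
        if not gate.included:
            continue
        for trial in trials:
            counts.append(trial_transitions(
                trial, lookahead_s=lookahead_s, delta_hz=delta_hz,
                **pipeline_kwargs))
    if not counts:
        warnings.warn("no responsive PN-odor pairs in dataset",
                      stacklevel=2)
    return counts


def compare_distributions(a: Sequence[int], b: Sequence[int]) -> TestResult:
    """Two-sample KS test on two distributions of transition counts."""
    return ks_two_sample(a, b)


def firing_rate_anova(ds: Dataset, epoch: str = "evoked",
                      window_s: float = RESPONSE_WINDOW_S,
                      spont_window_s: float = 2.0) -> dict:
    """Two-way ANOVA of per-trial mean firing rate on age x odor.

    ``epoch='evoked'`` takes the mean rate over [onset, onset + 4 s];
    ``'spontaneous'`` over the ``spont_window_s`` seconds before onset.
    """
    if epoch not in ("evoked", "spontaneous"):
        raise ValueError(f"unknown epoch {epoch!r}")
    rows = []
    for trial in ds.spike_trials:
        onset = trial.stimulus.onset_s
        if epoch == "evoked":
            lo, hi = onset, min(onset + window_s, trial.record_duration_s)
        else:
            lo, hi = max(0.0, onset - spont_window_s), onset
        if hi <= lo:
            continue
        n_spikes = int(np.sum((trial.spikes_s >= lo) & (trial.spikes_s < hi)))
        rows.append({"rate": n_spikes / (hi - lo),
                     "age_group": trial.animal.age_group,
                     "odor": trial.stimulus.odor_label})
    table = pd.DataFrame(rows)
    if table.empty or table["age_group"].nunique() < 2:
        raise ValueError("need spike trials from at least two age groups")
    return anova_two_way(table, "rate", "age_group", "odor")
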