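"""Synthetic datasets with the statistical structure the analyses
assume, with stored ground truth for parameter-recovery tests.

Three recording modalities are emulated:

* PN spike trains — inhomogeneous Poisson processes (thinning method)
  whose rate follows a piecewise-constant profile of excitatory and
  inhibitory epochs on top of a baseline; hatchling profiles use lower
  rates than adult ones.
* LFP traces — first-order autoregressive background noise (a smooth
  approximation of the 1/f-like spectra of field potentials that
  avoids spectral artifacts at band edges) plus an odor-locked
  oscillation burst: an amplitude-modulated sinusoid with a smooth
  raised-cosine on/off envelope and controllable frequency, amplitude,
  duration and onset latency. Burst frequency follows a drive map —
  afferent input from ``n`` antennal segments sets the oscillation
  frequency — and amplitude scales with segment count.
* EAG traces — difference-of-exponentials deflections with per-odor
  peak amplitudes (hexanol largest) and Gaussian noise; per-age mean
  profiles are equal by default, emulating the observed absence of
  age differences in peripheral tuning.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .datamodel import (AnalogTrial, AnimalMeta, Dataset, OdorStimulus,
                        SpikeTrainTrial)
from . import spikes as _spikes


@dataclass
class RateProfile:
    """Piecewise-constant firing-rate profile relative to odor onset.

    ``breakpoints_s`` are epoch edges (seconds from onset, ascending);
    segment ``i`` spans [breakpoints_s[i], breakpoints_s[i+1]) at
    ``rates_hz[i]``. Outside the breakpoints the rate is
    ``baseline_hz``.
    """

    breakpoints_s: Sequence[float]
    rates_hz: Sequence[float]
    baseline_hz: float = 5.0

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints_s, dtype=float)
        if len(bp) != len(self.rates_hz) + 1:
            raise ValueError("need len(breakpoints_s) == len(rates_hz) + 1")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(np.asarray(self.rates_hz) < 0) or self.baseline_hz < 0:
            raise ValueError("rates must be non-negative")

    def rate_at(self, t_s: np.ndarray, onset_s: float) -> np.ndarray:
        """Rate at absolute times ``t_s`` for a stimulus at
        ``onset_s``."""
        t = np.asarray(t_s, dtype=float) - onset_s
        bp = np.asarray(self.breakpoints_s)
        out = np.full(t.shape, self.baseline_hz, dtype=float)
        idx = np.searchsorted(bp, t, side="right") - 1
        inside = (idx >= 0) & (idx < len(self.rates_hz)) & (t < bp[-1])
        out[inside] = np.asarray(self.rates_hz)[idx[inside]]
        return out

    @property
    def max_rate_hz(self) -> float:
        return float(max(self.baseline_hz, *self.rates_hz)) \
            if len(self.rates_hz) else self.baseline_hz

    def ground_truth_transitions(self, onset_s: float = 2.0,
                                 record_duration_s: float = 7.0,
                                 dt_s: float = 0.001,
                                 delta_hz: float = 0.0,
                                 **pipeline_kwargs) -> int:
        """Transition count of the noiseless profile under the
        smoothing/detection/counting rules (rule-enumeration oracle;
        never hand-entered)."""
        n = int(np.round(record_duration_s / dt_s))
        t = np.arange(n) * dt_s
        rates = self.rate_at(t, onset_s)
        return _spikes.rate_profile_transitions(
            t, rates, onset_s, dt_s=dt_s, delta_hz=delta_hz,
            **pipeline_kwargs)


@dataclass
class DriveMap:
    """Phenomenological afferent-drive to oscillation-frequency map:
    f(n) = max(f_floor, f_ref - slope * (ref_segments - n)).

    Defaults: 20 Hz at the adult reference of 25 intact segments
    (midpoint of the adult 24-26 range) falling 0.52 Hz per removed
    segment, floored at 5 Hz.
    """

    f_ref_hz: float = 20.0
    ref_segments: int = 25
    slope_hz_per_segment: float = 0.52
    f_floor_hz: float = 5.0

    def frequency_hz(self, n_segments: int) -> float:
        f = self.f_ref_hz - self.slope_hz_per_segment * \
            (self.ref_segments - n_segments)
        return max(self.f_floor_hz, f)


#: Typical intact antennal-segment counts per age group (hatchlings
#: have 11-13 segments, adults 24-26).
AGE_SEGMENTS = {"hatchling": 12, "d10": 16, "d20": 20, "adult": 25}


def _default_profiles() -> Dict[str, RateProfile]:
    # Multiphasic excitation/inhibition epochs; hatchling rates lower
    # than adult, intermediate ages interpolated. Rates are package
    # choices (plausible locust PN burst rates); no measured values
    # are claimed.
    return {
        "adult": RateProfile([0.3, 1.0, 1.6, 2.4], [40.0, 2.0, 25.0],
                             baseline_hz=5.0),
        "d20": RateProfile([0.3, 1.0, 1.6, 2.4], [32.0, 1.5, 20.0],
                           baseline_hz=4.0),
        "d10": RateProfile([0.3, 1.0, 1.6, 2.4], [24.0, 1.0, 15.0],
                           baseline_hz=3.0),
        "hatchling": RateProfile([0.3, 1.0, 1.6, 2.4], [15.0, 0.5, 9.0],
                                 baseline_hz=2.0),
    }


def _default_eag_peaks() -> Dict[str, float]:
    # Mean peak deflections (mV); hexanol largest, the wheat-grass
    # volatiles strong, repellents and irrelevant chemicals weak.
    return {"hex": 2.0, "cis": 1.6, "wgj": 1.4, "hxa": 1.2, "fur": 0.8,
            "eth": 0.8, "cit": 0.7, "oct": 0.6, "pen": 0.6, "cyc": 0.5,
            "cam": 0.4}


@dataclass
class SynthConfig:
    """All generator parameters; identical (config, seed) pairs yield
    identical datasets."""

    seed: int = 0
    # spike trains: 6 trials per PN-odor pair, 2 s pre-onset baseline
    spike_trials: int = 6
    spike_onset_s: float = 2.0
    spike_record_s: float = 7.0
    profiles: Dict[str, RateProfile] = field(
        default_factory=_default_profiles)
    # LFP: 10 trials per odor
    lfp_trials: int = 10
    lfp_fs_hz: float = 1000.0
    lfp_record_s: float = 6.0
    lfp_onset_s: float = 2.0
    lfp_noise_sd_mV: float = 0.03
    lfp_burst_amp_mV: Dict[str, float] = field(default_factory=lambda: {
        "hatchling": 0.05, "d10": 0.10, "d20": 0.15, "adult": 0.20})
    lfp_burst_duration_s: Dict[str, float] = field(default_factory=lambda: {
        "hatchling": 0.8, "d10": 1.0, "d20": 1.2, "adult": 1.5})
    lfp_burst_latency_s: Dict[str, float] = field(default_factory=lambda: {
        "hatchling": 0.15, "d10": 0.20, "d20": 0.28, "adult": 0.35})
    lfp_latency_jitter_s: float = 0.02
    lfp_amp_jitter_frac: float = 0.10
    #: SD of the slow between-stage oscillation-frequency drift in the
    #: trim experiment (Hz); emulates physiological non-stationarity
    #: so per-stage frequency estimates are not artificially identical
    lfp_freq_drift_hz: float = 0.75
    # EAG
    eag_fs_hz: float = 500.0
    eag_record_s: float = 5.0
    eag_onset_s: float = 1.0
    eag_peak_means_mV: Dict[str, float] = field(
        default_factory=_default_eag_peaks)
    eag_peak_cv: float = 0.2
    eag_trace_noise_mV: float = 0.01
    eag_tau_rise_s: float = 0.05
    eag_tau_decay_s: float = 0.5
    eag_trials_per_odor: int = 1


def _thinned_poisson(rng: np.random.Generator, rate_fn, rate_max: float,
                     duration_s: float) -> np.ndarray:
    """Inhomogeneous Poisson spike times on [0, duration) by thinning
    a homogeneous process at ``rate_max``."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration_s)
    candidates = np.sort(rng.uniform(0.0, duration_s, size=n))
    keep = rng.uniform(0.0, rate_max, size=n) < rate_fn(candidates)
    times = candidates[keep]
    return np.unique(times)  # strict ascent (ties have probability 0)


def gen_pn_trials(profile: RateProfile, n_trials: int, seed: int,
                  onset_s: float = 2.0, record_duration_s: float = 7.0,
                  odor: str = "hex", cell_id: str = "pn1",
                  animal: Optional[AnimalMeta] = None
                  ) -> List[SpikeTrainTrial]:
    """Inhomogeneous Poisson spike trains following ``profile``.

    Each record includes the pre-onset baseline (2 s by default). An
    all-zero profile yields valid empty trains.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    animal = animal or AnimalMeta(animal_id="synth", age_group="adult")
    stim = OdorStimulus(odor_label=odor, onset_s=onset_s)
    trials = []
    for k in range(n_trials):
        spikes = _thinned_poisson(
            rng, lambda t: profile.rate_at(t, onset_s),
            profile.max_rate_hz, record_duration_s)
        trials.append(SpikeTrainTrial(
            spikes_s=spikes, record_duration_s=record_duration_s,
            stimulus=stim, trial_index=k + 1, cell_id=cell_id,
            animal=animal))
    return trials


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               phi: float = 0.98) -> np.ndarray:
    from scipy.signal import lfilter
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - phi ** 2), size=n)
    y_prev = rng.normal(0.0, sd)  # stationary start
    out, _ = lfilter([1.0], [1.0, -phi], innovations, zi=[phi * y_prev])
    return out


def _burst_envelope(n: int, ramp_frac: float = 0.25) -> np.ndarray:
    """Raised-cosine (Tukey) on/off envelope."""
    from scipy.signal.windows import tukey
    return tukey(n, alpha=2 * ramp_frac)


def gen_lfp_trials(n_segments: int, drive: DriveMap, cfg: SynthConfig,
                   n_trials: int, seed: int, age_group: str = "adult",
                   odor: str = "hex", side: str = "ipsi",
                   animal_id: str = "synth",
                   meta: Optional[dict] = None,
                   freq_offset_hz: float = 0.0) -> List[AnalogTrial]:
    """LFP trials: AR(1) background plus an odor-locked oscillation
    burst at the drive-map frequency for ``n_segments``.

    Burst amplitude scales linearly with the segment count relative to
    the drive map's reference, so trimming reduces amplitude as well
    as frequency.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if cfg.lfp_fs_hz <= 100:
        raise ValueError("lfp_fs_hz must exceed 100 Hz")
    rng = np.random.default_rng(seed)
    fs = cfg.lfp_fs_hz
    n = int(np.round(cfg.lfp_record_s * fs))
    t = np.arange(n) / fs
    freq = max(0.0, drive.frequency_hz(n_segments) + freq_offset_hz)
    amp0 = cfg.lfp_burst_amp_mV[age_group] * n_segments / drive.ref_segments
    duration = cfg.lfp_burst_duration_s[age_group]
    latency0 = cfg.lfp_burst_latency_s[age_group]
    stim = OdorStimulus(odor_label=odor, onset_s=cfg.lfp_onset_s)
    animal = AnimalMeta(animal_id=animal_id, age_group=age_group,
                        antennal_segments=n_segments)
    trials = []
    for k in range(n_trials):
        trace = _ar1_noise(rng, n, cfg.lfp_noise_sd_mV)
        latency = max(0.0, latency0 + rng.normal(
            0.0, cfg.lfp_latency_jitter_s))
        amp = amp0 * max(0.0, 1.0 + rng.normal(
            0.0, cfg.lfp_amp_jitter_frac))
        start = int(np.round((cfg.lfp_onset_s + latency) * fs))
        length = int(np.round(duration * fs))
        stop = min(start + length, n)
        if amp > 0 and stop > start:
            phase = rng.uniform(0.0, 2 * np.pi)
            seg_t = t[start:stop]
            burst = amp * _burst_envelope(stop - start) * \
                np.sin(2 * np.pi * freq * seg_t + phase)
            trace[start:stop] += burst
        trials.append(AnalogTrial(
            values_mV=trace, fs_hz=fs, modality="LFP", stimulus=stim,
            trial_index=k + 1, side=side, animal=animal,
            meta=dict(meta or {})))
    return trials


def _eag_kernel(t: np.ndarray, tau_rise: float, tau_decay: float
                ) -> np.ndarray:
    """Difference-of-exponentials deflection, normalized to peak 1."""
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k[t < 0] = 0.0
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_eag_trials(age_group: str, odor_panel: Sequence[str],
                   cfg: SynthConfig, seed: int, n_animals: int = 1,
                   animal_prefix: str = "eag",
                   peak_shift_mV: float = 0.0) -> List[AnalogTrial]:
    """EAG trials for ``n_animals`` animals across an odor panel.

    Per-animal, per-odor peak amplitudes are drawn around the
    configured odor means (coefficient of variation ``eag_peak_cv``);
    deflections are negative-going, as EAG responses conventionally
    are. ``peak_shift_mV`` adds a common offset to every odor mean and
    exists so tests can inject a known age effect.
    """
    if not odor_panel:
        raise ValueError("odor panel must be non-empty")
    rng = np.random.default_rng(seed)
    fs = cfg.eag_fs_hz
    n = int(np.round(cfg.eag_record_s * fs))
    t = np.arange(n) / fs
    kernel = _eag_kernel(t - cfg.eag_onset_s, cfg.eag_tau_rise_s,
                         cfg.eag_tau_decay_s)
    trials = []
    for a in range(n_animals):
        animal = AnimalMeta(animal_id=f"{animal_prefix}{a + 1:02d}",
                            age_group=age_group)
        for odor in odor_panel:
            mean = cfg.eag_peak_means_mV[odor] + peak_shift_mV
            for k in range(cfg.eag_trials_per_odor):
                peak = max(0.0, rng.normal(mean, cfg.eag_peak_cv * mean))
                trace = -peak * kernel + rng.normal(
                    0.0, cfg.eag_trace_noise_mV, size=n)
                trials.append(AnalogTrial(
                    values_mV=trace, fs_hz=fs, modality="EAG",
                    stimulus=OdorStimulus(odor_label=odor,
                                          onset_s=cfg.eag_onset_s),
                    trial_index=k + 1, animal=animal))
    return trials


def gen_pn_dataset(age_groups: Sequence[str], n_cells: int,
                   odors: Sequence[str], cfg: SynthConfig, seed: int
                   ) -> Dataset:
    """Spike-train dataset: ``n_cells`` PNs per age group, the full
    trial count per PN-odor pair, rates from the per-age profiles."""
    ds = Dataset(manifest={"provenance": "synthetic", "seed": seed})
    root = np.random.default_rng(seed)
    for age in age_groups:
        profile = cfg.profiles[age]
        for c in range(n_cells):
            animal = AnimalMeta(animal_id=f"{age}_an{c + 1:02d}",
                                age_group=age,
                                antennal_segments=AGE_SEGMENTS[age])
            for odor in odors:
                sub = int(root.integers(0, 2 ** 31 - 1))
                ds.spike_trials.extend(gen_pn_trials(
                    profile, cfg.spike_trials, sub,
                    onset_s=cfg.spike_onset_s,
                    record_duration_s=cfg.spike_record_s, odor=odor,
                    cell_id=f"{age}_pn{c + 1:02d}", animal=animal))
    return ds


def gen_trim_experiment(cut_schedule: Sequence[int], drive: DriveMap,
                        cfg: SynthConfig, seed: int,
                        animal_id: str = "trim01",
                        odor: str = "hex") -> Dataset:
    """Antennal-trimming experiment: at each stage of the schedule the
    ipsilateral antenna has the scheduled segment count while the
    contralateral antenna stays at the initial (full) count; 10 LFP
    trials are generated per side per stage.

    The schedule must be non-increasing (segments are removed, never
    regrown). The drive-map ground truth is stored in the manifest.
    """
    schedule = list(cut_schedule)
    if not schedule:
        raise ValueError("cut_schedule must be non-empty")
    if any(b > a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("cut_schedule must be non-increasing")
    full = schedule[0]
    root = np.random.default_rng(seed)
    ds = Dataset(manifest={
        "provenance": "synthetic trim experiment",
        "seed": seed,
        "full_segments": full,
        "cut_schedule": schedule,
        "ground_truth_slope_hz_per_cut": -drive.slope_hz_per_segment,
    })
    for stage, n_seg in enumerate(schedule):
        meta = {"stage": stage, "cuts": full - n_seg}
        # slow physiological drift is a property of the preparation at
        # that stage, so both sides share it
        drift = root.normal(0.0, cfg.lfp_freq_drift_hz)
        for side, seg in (("ipsi", n_seg), ("contra", full)):
            sub = int(root.integers(0, 2 ** 31 - 1))
            ds.analog_trials.extend(gen_lfp_trials(
                seg, drive, cfg, cfg.lfp_trials, sub,
                age_group="adult", odor=odor, side=side,
                animal_id=animal_id, meta=meta, freq_offset_hz=drift))
    return ds


def gen_trim_cohort(n_antennae: int, cut_schedule: Sequence[int],
                    drive: DriveMap, cfg: SynthConfig, seed: int,
                    odor: str = "hex") -> Dataset:
    """Trim experiments for a cohort of antennae pooled into one
    dataset (the study design uses 7 antennae)."""
    if n_antennae < 1:
        raise ValueError("n_antennae must be >= 1")
    root = np.random.default_rng(seed)
    ds = Dataset(manifest={
        "provenance": "synthetic trim cohort",
        "seed": seed,
        "n_antennae": n_antennae,
        "cut_schedule": list(cut_schedule),
        "ground_truth_slope_hz_per_cut": -drive.slope_hz_per_segment,
    })
    for a in range(n_antennae):
        sub = int(root.integers(0, 2 ** 31 - 1))
        part = gen_trim_experiment(cut_schedule, drive, cfg, sub,
                                   animal_id=f"trim{a + 1:02d}",
                                   odor=odor)
        ds.analog_trials.extend(part.analog_trials)
    return ds


def gen_lfp_dataset(age_groups: Sequence[str], cfg: SynthConfig,
                    drive: Optional[DriveMap] = None, seed: int = 0,
                    odor: str = "hex") -> Dataset:
    """Per-age LFP dataset at each age group's typical segment count."""
    drive = drive or DriveMap()
    ds = Dataset(manifest={"provenance": "synthetic", "seed": seed})
    root = np.random.default_rng(seed)
    for age in age_groups:
        sub = int(root.integers(0, 2 ** 31 - 1))
        ds.analog_trials.extend(gen_lfp_trials(
            AGE_SEGMENTS[age], drive, cfg, cfg.lfp_trials, sub,
            age_group=age, odor=odor, side="ipsi",
            animal_id=f"{age}_lfp01"))
    return ds


def gen_eag_dataset(groups: Dict[str, int], cfg: SynthConfig,
                    seed: int, odor_panel: Optional[Sequence[str]] = None,
                    shifts_mV: Optional[Dict[str, float]] = None
                    ) -> Dataset:
    """EAG dataset with ``groups`` mapping age_group -> n_animals."""
    odor_panel = list(odor_panel or cfg.eag_peak_means_mV)
    root = np.random.default_rng(seed)
    ds = Dataset(manifest={"provenance": "synthetic", "seed": seed})
    for age, n_animals in groups.items():
        sub = int(root.integers(0, 2 ** 31 - 1))
        ds.analog_trials.extend(gen_eag_trials(
            age, odor_panel, cfg, sub, n_animals=n_animals,
            animal_prefix=f"{age}_",
            peak_shift_mV=(shifts_mV or {}).get(age, 0.0)))
    return ds
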