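"""Trial-structured data model for developmental locust olfactory recordings.

The study design is trial-structured: an odor pulse (1 s by default) is
delivered to an antenna while one of three signals is recorded — spike
times from an antennal-lobe projection neuron (PN), a local field
potential (LFP) from the mushroom-body calyx, or an electroantennogram
(EAG) from the antenna. Every trial carries stimulus metadata (odor
label, onset, duration) and animal metadata (age group, antennal-segment
count where relevant).

Units are fixed at the API boundary: seconds, millivolts, hertz. The
time axis starts at t = 0 at trace start; the stimulus position is
carried as ``onset_s`` rather than re-zeroing the trace, because the
analyses need pre-stimulus baseline windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

#: Odor panel used across the study. Free-text labels are also accepted.
ODOR_PANEL = ("hex", "cis", "hxa", "oct", "cyc", "fur", "eth", "cit",
              "pen", "cam", "wgj")

#: Developmental stages: freshly hatched (1st instar), 10 days (3rd
#: instar), 20 days (5th instar) and adult (~35 days).
AGE_GROUPS = ("hatchling", "d10", "d20", "adult")

MODALITIES = ("LFP", "EAG", "Vm")
SIDES = ("ipsi", "contra", "none")

#: Upper edge of the LFP analysis band (Hz); LFP sampling must satisfy
#: Nyquist for this edge.
LFP_BAND_HIGH_HZ = 50.0


@dataclass
class OdorStimulus:
    """A square odor pulse delivered within a constant air stream."""

    odor_label: str
    onset_s: float
    duration_s: float = 1.0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnimalMeta:
    """Per-animal metadata.

    ``antennal_segments`` is the number of intact sensory-neuron-bearing
    antennal segments (hatchlings ~11-13, adults 24-26); it is ``None``
    for experiments where it was not tracked.
    """

    animal_id: str
    age_group: str = "adult"
    antennal_segments: Optional[int] = None


@dataclass
class SpikeTrainTrial:
    """Sorted spike times for one PN-odor-trial."""

    spikes_s: np.ndarray
    record_duration_s: float
    stimulus: OdorStimulus
    trial_index: int
    cell_id: str
    animal: AnimalMeta
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes_s = np.asarray(self.spikes_s, dtype=float)


@dataclass
class AnalogTrial:
    """Uniformly sampled voltage trace (LFP, EAG or membrane potential)."""

    values_mV: np.ndarray
    fs_hz: float
    modality: str
    stimulus: OdorStimulus
    trial_index: int
    animal: AnimalMeta
    side: str = "none"
    #: free-form annotations (e.g. trim-experiment stage and cut count)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_mV = np.asarray(self.values_mV, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.values_mV) / self.fs_hz

    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values_mV)) / self.fs_hz


Trial = Union[SpikeTrainTrial, AnalogTrial]


@dataclass
class Dataset:
    """A collection of trials plus a manifest metadata block."""

    spike_trials: list = field(default_factory=list)
    analog_trials: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def trials(self) -> list:
        return list(self.spike_trials) + list(self.analog_trials)

    def analog(self, modality: Optional[str] = None,
               side: Optional[str] = None) -> list:
        """Analog trials filtered by modality and/or recording side."""
        out = self.analog_trials
        if modality is not None:
            out = [t for t in out if t.modality == modality]
        if side is not None:
            out = [t for t in out if t.side == side]
        return out


def _trial_name(trial: Trial) -> str:
    if isinstance(trial, SpikeTrainTrial):
        return (f"spike trial (cell={trial.cell_id}, "
                f"odor={trial.stimulus.odor_label}, "
                f"trial={trial.trial_index})")
    return (f"{trial.modality} trial (animal={trial.animal.animal_id}, "
            f"odor={trial.stimulus.odor_label}, side={trial.side}, "
            f"trial={trial.trial_index})")


def _validate_stimulus(stim: OdorStimulus, name: str, out: list) -> None:
    if not stim.odor_label:
        out.append(f"{name}: odor_label is empty")
    if stim.onset_s < 0:
        out.append(f"{name}: stimulus onset_s must be non-negative "
                   f"(got {stim.onset_s})")
    if stim.duration_s <= 0:
        out.append(f"{name}: stimulus duration_s must be positive "
                   f"(got {stim.duration_s})")


def _validate_animal(animal: AnimalMeta, name: str, out: list) -> None:
    if animal.age_group not in AGE_GROUPS:
        out.append(f"{name}: unknown age_group {animal.age_group!r} "
                   f"(expected one of {AGE_GROUPS})")
    n = animal.antennal_segments
    if n is not None and not (1 <= n <= 30):
        out.append(f"{name}: antennal_segments must be in [1, 30] "
                   f"(got {n})")


def validate_dataset(ds: Dataset) -> list:
    """Check every type invariant; return a list of violation strings.

    Violations are returned rather than raised so that a validation
    report can name every problem at once. An empty list means the
    dataset is valid.
    """
    out: list = []
    for trial in ds.spike_trials:
        name = _trial_name(trial)
        _validate_stimulus(trial.stimulus, name, out)
        _validate_animal(trial.animal, name, out)
        if trial.trial_index < 1:
            out.append(f"{name}: trial_index must be 1-based")
        s = trial.spikes_s
        if len(s) and np.any(np.diff(s) <= 0):
            out.append(f"{name}: spike times not strictly ascending")
        if len(s) and s[0] < 0:
            out.append(f"{name}: spike times must be non-negative")
        if len(s) and s[-1] > trial.record_duration_s:
            out.append(f"{name}: spike time beyond record_duration_s")
        if trial.stimulus.offset_s > trial.record_duration_s:
            out.append(f"{name}: stimulus extends past end of record")
    for trial in ds.analog_trials:
        name = _trial_name(trial)
        _validate_stimulus(trial.stimulus, name, out)
        _validate_animal(trial.animal, name, out)
        if trial.trial_index < 1:
            out.append(f"{name}: trial_index must be 1-based")
        if trial.modality not in MODALITIES:
            out.append(f"{name}: unknown modality {trial.modality!r}")
        if trial.side not in SIDES:
            out.append(f"{name}: unknown side {trial.side!r}")
        if trial.fs_hz <= 0:
            out.append(f"{name}: fs_hz must be positive")
        elif trial.modality == "LFP" and trial.fs_hz <= 2 * LFP_BAND_HIGH_HZ:
            out.append(f"{name}: fs_hz = {trial.fs_hz} violates the "
                       f"Nyquist requirement fs > {2 * LFP_BAND_HIGH_HZ} Hz "
                       f"for the {LFP_BAND_HIGH_HZ} Hz band edge")
    # trial_index uniqueness within (recording unit, odor, modality, side)
    seen: dict = {}
    for trial in ds.trials:
        stage = trial.meta.get("stage")
        if isinstance(trial, SpikeTrainTrial):
            key = ("spike", trial.cell_id, trial.stimulus.odor_label,
                   stage, trial.trial_index)
        else:
            key = (trial.modality, trial.animal.animal_id,
                   trial.stimulus.odor_label, trial.side, stage,
                   trial.trial_index)
        if key in seen:
            out.append(f"duplicate trial_index: {_trial_name(trial)}")
        seen[key] = True
    return out
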