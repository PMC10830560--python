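"""On-disk dataset format: one JSON manifest plus per-trial text files.

The format is deliberately plain text so datasets are diffable and have
no binary dependencies:

* ``manifest.json`` — schema version, optional generator provenance,
  and one entry per trial with its metadata and file name.
* spike files — one spike time per line, in seconds.
* analog files — one sample per line, in millivolts (a two-column
  ``time,value`` layout is also accepted; the time column is ignored on
  load beyond a uniformity check).

Files may declare other units in their manifest entry (``time_units``:
``s``/``ms``; ``value_units``: ``mV``/``uV``/``V``); values are
converted to seconds/millivolts on load so the in-memory model is
always in canonical units.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .datamodel import (AnalogTrial, AnimalMeta, Dataset, OdorStimulus,
                        SpikeTrainTrial, validate_dataset)

SCHEMA_VERSION = 1

_TIME_SCALE = {"s": 1.0, "ms": 1e-3}
_VALUE_SCALE = {"mV": 1.0, "uV": 1e-3, "V": 1e3}


class DatasetFormatError(Exception):
    """Raised when a dataset directory does not follow the format."""


class DatasetValidationError(Exception):
    """Raised when a loaded dataset violates a model invariant."""


def _stimulus_record(stim: OdorStimulus) -> dict:
    return {"odor": stim.odor_label, "onset_s": stim.onset_s,
            "duration_s": stim.duration_s}


def _animal_record(animal: AnimalMeta) -> dict:
    rec = {"animal_id": animal.animal_id, "age_group": animal.age_group}
    if animal.antennal_segments is not None:
        rec["antennal_segments"] = int(animal.antennal_segments)
    return rec


def save_dataset(ds: Dataset, path: Union[str, Path]) -> None:
    """Write ``ds`` to ``path`` in the manifest + text-file layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trial in enumerate(ds.spike_trials):
        fname = (f"spikes_{trial.cell_id}_{trial.stimulus.odor_label}"
                 f"_t{trial.trial_index:02d}_{i:04d}.txt")
        np.savetxt(path / fname, np.asarray(trial.spikes_s), fmt="%.9f")
        entry = {"kind": "spike", "file": fname,
                 "record_duration_s": trial.record_duration_s,
                 "trial_index": trial.trial_index,
                 "cell_id": trial.cell_id}
        entry.update(_stimulus_record(trial.stimulus))
        entry.update(_animal_record(trial.animal))
        if trial.meta:
            entry["extra"] = trial.meta
        entries.append(entry)
    for i, trial in enumerate(ds.analog_trials):
        fname = (f"{trial.modality.lower()}_{trial.animal.animal_id}"
                 f"_{trial.stimulus.odor_label}_{trial.side}"
                 f"_t{trial.trial_index:02d}_{i:04d}.txt")
        np.savetxt(path / fname, np.asarray(trial.values_mV), fmt="%.9f")
        entry = {"kind": "analog", "file": fname,
                 "fs_hz": trial.fs_hz, "modality": trial.modality,
                 "side": trial.side, "trial_index": trial.trial_index}
        entry.update(_stimulus_record(trial.stimulus))
        entry.update(_animal_record(trial.animal))
        if trial.meta:
            entry["extra"] = trial.meta
        entries.append(entry)
    manifest = dict(ds.manifest)
    manifest.setdefault("schema_version", SCHEMA_VERSION)
    manifest["trials"] = entries
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_column_file(fpath: Path) -> np.ndarray:
    data = np.loadtxt(fpath, delimiter=None, ndmin=2)
    if data.size == 0:
        return np.empty(0)
    if data.shape[1] == 1:
        return data[:, 0]
    if data.shape[1] == 2:  # time,value layout: keep the value column
        return data[:, 1]
    raise DatasetFormatError(f"{fpath}: expected 1 or 2 columns, "
                             f"got {data.shape[1]}")


def _entry_animal(entry: dict) -> AnimalMeta:
    return AnimalMeta(animal_id=entry.get("animal_id", "unknown"),
                      age_group=entry.get("age_group", "adult"),
                      antennal_segments=entry.get("antennal_segments"))


def _entry_stimulus(entry: dict, tscale: float) -> OdorStimulus:
    return OdorStimulus(odor_label=entry["odor"],
                        onset_s=entry["onset_s"] * tscale,
                        duration_s=entry["duration_s"] * tscale)


def load_dataset(path: Union[str, Path]) -> Dataset:
    """Load a dataset directory; validate and convert to canonical units.

    Raises :class:`DatasetFormatError` when the manifest is missing or
    malformed and :class:`DatasetValidationError` (listing each
    offending trial) when the content violates a model invariant.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise DatasetFormatError(f"no manifest.json in {path}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"malformed manifest: {exc}") from exc
    if "trials" not in manifest:
        raise DatasetFormatError("manifest lacks a 'trials' list")

    ds = Dataset(manifest={k: v for k, v in manifest.items()
                           if k != "trials"})
    for entry in manifest["trials"]:
        tscale = _TIME_SCALE[entry.get("time_units", "s")]
        vscale = _VALUE_SCALE[entry.get("value_units", "mV")]
        fpath = path / entry["file"]
        if not fpath.exists():
            raise DatasetFormatError(f"referenced file missing: {fpath}")
        values = _read_column_file(fpath)
        if entry["kind"] == "spike":
            ds.spike_trials.append(SpikeTrainTrial(
                spikes_s=values * tscale,
                record_duration_s=entry["record_duration_s"] * tscale,
                stimulus=_entry_stimulus(entry, tscale),
                trial_index=int(entry["trial_index"]),
                cell_id=entry["cell_id"],
                animal=_entry_animal(entry),
                meta=entry.get("extra", {})))
        elif entry["kind"] == "analog":
            ds.analog_trials.append(AnalogTrial(
                values_mV=values * vscale,
                fs_hz=entry["fs_hz"] / tscale,
                modality=entry["modality"],
                stimulus=_entry_stimulus(entry, tscale),
                trial_index=int(entry["trial_index"]),
                side=entry.get("side", "none"),
                animal=_entry_animal(entry),
                meta=entry.get("extra", {})))
        else:
            raise DatasetFormatError(f"unknown trial kind {entry['kind']!r}")

    violations = validate_dataset(ds)
    if violations:
        raise DatasetValidationError("; ".join(violations))
    return ds
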