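"""Electroantennogram (EAG) tuning analysis.

EAGs sum the receptor potentials of the antennal OSN population. The
analysis extracts per-odor peak deflections, normalizes each animal's
panel by its own hexanol response (hexanol evokes the largest
deflection, so normalized hex amplitude is 1 by construction), and
compares age groups odor-by-odor with Bonferroni-corrected two-sample
t-tests plus a dummy-coded OLS of amplitude on age and stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalogTrial, Dataset
from .stats import bonferroni_alpha, ols_categorical, t_two_sample

logger = logging.getLogger(__name__)

REFERENCE_ODOR = "hex"


@dataclass
class EAGSummary:
    animal_id: str
    age_group: str
    raw_peaks_mV: Dict[str, float]
    normalized: Dict[str, float]


def eag_peak_amplitude(trial: AnalogTrial,
                       response_window_s: float = 2.0) -> float:
    """Peak deflection from baseline in the response window.

    Baseline is the mean of all pre-onset samples; the peak is the
    maximum absolute deviation from it within
    [onset, onset + response_window_s]. Absolute deviation keeps the
    measure polarity-agnostic (EAG deflections are conventionally
    negative).
    """
    onset_idx = int(np.round(trial.stimulus.onset_s * trial.fs_hz))
    if onset_idx < 1:
        raise ValueError("no pre-onset samples: baseline undefined")
    end_idx = int(np.round((trial.stimulus.onset_s + response_window_s)
                           * trial.fs_hz))
    if end_idx > len(trial.values_mV):
        raise ValueError("response window extends past end of trace")
    baseline = float(np.mean(trial.values_mV[:onset_idx]))
    window = trial.values_mV[onset_idx:end_idx]
    return float(np.max(np.abs(window - baseline)))


def normalize_panel(peaks: Dict[str, float],
                    reference: str = REFERENCE_ODOR) -> Dict[str, float]:
    """Divide every odor's peak by the same animal's reference (hex)
    peak."""
    if reference not in peaks:
        raise ValueError(f"reference odor {reference!r} missing from panel")
    ref = peaks[reference]
    if ref <= 0:
        raise ValueError(f"reference odor {reference!r} peak must be "
                         f"positive (got {ref})")
    return {odor: peak / ref for odor, peak in peaks.items()}


def summarize_dataset(ds: Dataset, response_window_s: float = 2.0,
                      reference: str = REFERENCE_ODOR) -> List[EAGSummary]:
    """Per-animal EAG summaries: trial-averaged raw peaks per odor and
    the hex-normalized panel."""
    per_animal: Dict[str, Dict[str, List[float]]] = {}
    ages: Dict[str, str] = {}
    for trial in ds.analog(modality="EAG"):
        aid = trial.animal.animal_id
        ages[aid] = trial.animal.age_group
        per_animal.setdefault(aid, {}).setdefault(
            trial.stimulus.odor_label, []).append(
                eag_peak_amplitude(trial, response_window_s))
    out = []
    for aid in sorted(per_animal):
        raw = {odor: float(np.mean(vals))
               for odor, vals in per_animal[aid].items()}
        out.append(EAGSummary(animal_id=aid, age_group=ages[aid],
                              raw_peaks_mV=raw,
                              normalized=normalize_panel(raw, reference)))
    return out


def compare_age_groups(group_a: Sequence[EAGSummary],
                       group_b: Sequence[EAGSummary],
                       odors: Optional[Sequence[str]] = None,
                       variant: str = "welch",
                       family_alpha: float = 0.05,
                       bonferroni_m: Optional[int] = None,
                       reference: str = REFERENCE_ODOR) -> pd.DataFrame:
    """Per-odor two-sample t-tests between two age groups on normalized
    amplitudes, with Bonferroni correction.

    The reference odor is excluded (its normalized value is 1 for every
    animal). The corrected alpha defaults to family_alpha divided by
    the number of odors actually tested; ``bonferroni_m`` overrides the
    divisor. Odors missing from either group are skipped with a logged
    warning.
    """
    if odors is None:
        odors = sorted({o for s in list(group_a) + list(group_b)
                        for o in s.normalized} - {reference})
    rows = []
    for odor in odors:
        if odor == reference:
            continue
        a = [s.normalized[odor] for s in group_a if odor in s.normalized]
        b = [s.normalized[odor] for s in group_b if odor in s.normalized]
        if len(a) < 2 or len(b) < 2:
            logger.warning("odor %r missing or underpowered in one group; "
                           "skipped", odor)
            continue
        res = t_two_sample(a, b, variant=variant)
        rows.append({"odor": odor, "t": res.statistic, "p": res.p_value,
                     "df": res.df, "n_a": len(a), "n_b": len(b)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    m = bonferroni_m if bonferroni_m is not None else len(table)
    alpha = bonferroni_alpha(m, family_alpha)
    table["corrected_alpha"] = alpha
    table["significant"] = table["p"] < alpha
    return table


def long_table(summaries: Sequence[EAGSummary],
               use_normalized: bool = True) -> pd.DataFrame:
    """Long-format amplitude table with one row per (animal, odor)."""
    rows = []
    for s in summaries:
        values = s.normalized if use_normalized else s.raw_peaks_mV
        for odor, amp in values.items():
            rows.append({"amplitude": amp, "age_group": s.age_group,
                         "odor": odor, "animal_id": s.animal_id})
    return pd.DataFrame(rows)


def fit_amplitude_ols(table: pd.DataFrame):
    """OLS of amplitude on categorical age and stimulus:
    amplitude ~ C(age_group) + C(odor).

    Returns the statsmodels results object; the age coefficient, its
    SE and p-value are in ``params`` / ``bse`` / ``pvalues`` under the
    dummy-coded age term.
    """
    table = pd.DataFrame(table)
    if table["age_group"].nunique() < 2 or table["odor"].nunique() < 2:
        raise ValueError("need >= 2 age levels and >= 2 odors")
    return ols_categorical(table, "amplitude", ["age_group", "odor"])


def age_coefficient(fit) -> dict:
    """Extract the age dummy coefficient from an amplitude OLS fit."""
    name = [n for n in fit.params.index if n.startswith("C(age_group)")]
    if len(name) != 1:
        raise ValueError("expected exactly one age dummy term; "
                         f"got {name}")
    name = name[0]
    return {"coefficient": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "p": float(fit.pvalues[name]),
            "n": int(fit.nobs),
            "r2": float(fit.rsquared)}
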