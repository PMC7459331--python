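"""Bursting-cell identification and the NB/AB/qHB/HB taxonomy.

A cell is *bursting responsive* to a stimulus when its trial-averaged
Δf/f response reaches the indicator threshold (Cal-520: 1.5, GCaMP6f:
1.0, comparisons inclusive).  Against the stimulus structure of the
paradigm (complex sounds and their constituent tones) the per-stimulus
flags induce the taxonomy:

* HB (holistic bursting): bursts to a complex sound but to none of its
  constituent tones (and to no other tone);
* qHB (quasi-holistic): bursts to a complex sound plus one or several
  (but not all) of its constituent tones;
* AB (analytic bursting): bursts only to one or a few pure tones;
* NB (non-bursting): bursts to nothing.

For multi-chord paradigms the chord driving the label is recorded as
``chord_index``; a cell qualifying as quasi-holistic for both chords is
assigned to chord 1 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import Stimulus

__all__ = [
    "BurstCriteria",
    "CellLabel",
    "StimulusStructure",
    "NonlinearitySummary",
    "is_bursting_responsive",
    "classify_cell",
    "classify_population",
    "nonlinearity_summary",
]

logger = logging.getLogger(__name__)

THRESHOLDS = {"Cal520": 1.5, "GCaMP6f": 1.0}


@dataclass(frozen=True)
class BurstCriteria:
    """The fixed indicator thresholds of the method."""

    theta_cal520: float = 1.5
    theta_gcamp6f: float = 1.0
    level: str = "trial_averaged"  # or "single_trial"


@dataclass(frozen=True)
class CellLabel:
    cell_id: str
    label: str  # NB | AB | qHB | HB
    chord_index: int | None
    bursting_stimuli: frozenset


def is_bursting_responsive(trial_averaged_amp: float, indicator: str) -> bool:
    """Inclusive threshold test on a (trial-averaged) Δf/f amplitude."""
    if not np.isfinite(trial_averaged_amp):
        raise ValueError("amplitude must be finite")
    try:
        theta = THRESHOLDS[indicator]
    except KeyError:
        raise ValueError(f"unknown indicator {indicator!r}") from None
    return bool(trial_averaged_amp >= theta)


class StimulusStructure:
    """Complex sounds and their constituent tones for one paradigm."""

    def __init__(self, stimuli: list[Stimulus], exclusive_components: bool = True):
        self.complexes = [s for s in stimuli if s.is_complex]
        self.tones = [s.stim_id for s in stimuli if not s.is_complex]
        if exclusive_components and len(self.complexes) > 1:
            seen: dict[str, str] = {}
            for c in self.complexes:
                for t in c.components:
                    if t in seen:
                        raise ValueError(
                            f"tone {t!r} listed in both {seen[t]!r} and {c.stim_id!r}"
                        )
                    seen[t] = c.stim_id
            orphans = [t for t in self.tones if t not in seen]
            if orphans:
                raise ValueError(f"tones {orphans} belong to no complex sound")
        self.all_stimuli = [c.stim_id for c in self.complexes] + self.tones

    def chord_index(self, stim_id: str) -> int:
        for i, c in enumerate(self.complexes, start=1):
            if c.stim_id == stim_id:
                return i
        raise KeyError(stim_id)


def classify_cell(bursting_flags: dict, structure: StimulusStructure, cell_id: str = "") -> CellLabel:
    """Assign the taxonomy label from per-stimulus bursting flags.

    ``bursting_flags`` maps stimulus id -> bool at the trial-averaged
    level.  Complex sounds are examined in structure order, so a cell
    quasi-holistic for both chords is labelled for chord 1.
    """
    bursting = frozenset(s for s, flag in bursting_flags.items() if flag)
    for s in bursting:
        if s not in structure.all_stimuli:
            raise ValueError(f"stimulus {s!r} not in the declared structure")

    for i, cx in enumerate(structure.complexes, start=1):
        if cx.stim_id not in bursting:
            continue
        comps = [t for t in cx.components if t in bursting_flags]
        comp_hits = [t for t in comps if t in bursting]
        chord_index = i if len(structure.complexes) > 1 else None
        if not comp_hits:
            return CellLabel(cell_id, "HB", chord_index, bursting)
        if len(comp_hits) == len(comps):
            # A complex sound plus all its components has no named
            # category; quasi-holistic is the closest.
            logger.warning(
                "cell %s bursts to %s and all its components; labelling qHB",
                cell_id, cx.stim_id,
            )
        return CellLabel(cell_id, "qHB", chord_index, bursting)

    if bursting:
        return CellLabel(cell_id, "AB", None, bursting)
    return CellLabel(cell_id, "NB", None, frozenset())


def classify_population(
    trial_avg: pd.DataFrame,
    structure: StimulusStructure,
    indicator: str,
) -> pd.DataFrame:
    """Label every cell from its trial-averaged response table.

    ``trial_avg`` has columns (cell_id, stimulus_id, amplitude), one row
    per cell x stimulus.  Returns a DataFrame with columns (cell_id,
    label, chord_index, bursting_stimuli).
    """
    rows = []
    for cell_id, grp in trial_avg.groupby("cell_id", sort=True):
        flags = {
            str(r.stimulus_id): is_bursting_responsive(float(r.amplitude), indicator)
            for r in grp.itertuples()
        }
        lab = classify_cell(flags, structure, cell_id=str(cell_id))
        rows.append(
            {
                "cell_id": lab.cell_id,
                "label": lab.label,
                "chord_index": lab.chord_index,
                "bursting_stimuli": ";".join(sorted(lab.bursting_stimuli)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NonlinearitySummary:
    """Holistic-cell response decomposition.

    Per cell: the trial-averaged amplitude of the preferred chord, the
    sum of its four constituent-tone amplitudes, the best single-tone
    amplitude, and the non-preferred chord amplitude.  Cohort rows carry
    median and quartiles of each quantity.
    """

    per_cell: pd.DataFrame
    cohort: pd.DataFrame


def nonlinearity_summary(
    labels: pd.DataFrame,
    trial_avg: pd.DataFrame,
    structure: StimulusStructure,
) -> NonlinearitySummary:
    """Quantify nonlinear summation for HB cells in a chord paradigm."""
    if len(structure.complexes) < 2:
        raise ValueError("nonlinearity summary needs a two-chord structure")
    amp = trial_avg.set_index(["cell_id", "stimulus_id"])["amplitude"]
    hb = labels[labels["label"] == "HB"]
    rows = []
    for r in hb.itertuples():
        ci = int(r.chord_index)
        pref = structure.complexes[ci - 1]
        nonpref = structure.complexes[2 - ci] if len(structure.complexes) == 2 else None
        try:
            pref_amp = float(amp[(r.cell_id, pref.stim_id)])
            comp_amps = [float(amp[(r.cell_id, t)]) for t in pref.components]
            tone_amps = [float(amp[(r.cell_id, t)]) for t in structure.tones]
            nonpref_amp = float(amp[(r.cell_id, nonpref.stim_id)]) if nonpref else np.nan
        except KeyError as e:
            raise ValueError(f"missing amplitude for cell {r.cell_id}: {e}") from None
        sum_amp = float(np.sum(comp_amps))
        rows.append(
            {
                "cell_id": r.cell_id,
                "chord_index": ci,
                "preferred_chord_amp": pref_amp,
                "sum_of_components_amp": sum_amp,
                "best_tone_amp": float(np.max(tone_amps)),
                "nonpreferred_chord_amp": nonpref_amp,
                # ratio 1 = linear summation; equal responses everywhere
                # give 1/4 (not HB-consistent); holistic cells exceed 1
                "linearity_ratio": pref_amp / sum_amp if sum_amp > 0 else np.inf,
            }
        )
    per_cell = pd.DataFrame(rows)
    cohort_rows = []
    for col in (
        "preferred_chord_amp",
        "sum_of_components_amp",
        "best_tone_amp",
        "nonpreferred_chord_amp",
    ):
        x = per_cell[col].to_numpy(dtype=float) if len(per_cell) else np.empty(0)
        cohort_rows.append(
            {
                "quantity": col,
                "median": float(np.median(x)) if x.size else np.nan,
                "q1": float(np.percentile(x, 25)) if x.size else np.nan,
                "q3": float(np.percentile(x, 75)) if x.size else np.nan,
                "n": int(x.size),
            }
        )
    return NonlinearitySummary(per_cell=per_cell, cohort=pd.DataFrame(cohort_rows))
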