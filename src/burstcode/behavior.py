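"""Licking-behaviour scoring.

Sound-evoked and spontaneous lick probabilities, the 20-droplet
effective-trial rule, the trained criterion (evoked probability >= 80%),
and the subsession analysis contrasting burst reliability with
motivational decay over consecutive 10-trial bins.

Scoring rules
-------------
* A successful evoked lick is a lick-bout initiation within 1000 ms of
  sound onset; only the first in-window contact counts, and on two-spout
  rigs it must land on the assigned spout.  A bout that began before the
  sound and merely continues into the window is not evoked.
* A pumped droplet remains at the spout until the first subsequent lick
  consumes it (or the next trial's droplet replaces it).  Only trials up
  to the consumption of the 20th droplet are effective and enter the
  session probability.
* Spontaneous licking is the fraction of 1000 ms inter-trial bins
  containing a bout initiation, excluding the 1000 ms post-stimulus
  scoring window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import LickSeries, Trial

__all__ = [
    "SessionScore",
    "SubsessionResult",
    "evoked_lick_probability",
    "spontaneous_lick_probability",
    "subsession_analysis",
]

TRAINED_CRITERION = 0.8
EVOKED_WINDOW_MS = 1000.0
N_DROPLETS = 20


@dataclass(frozen=True)
class SessionScore:
    evoked_lick_prob: float
    n_effective_trials: int
    n_successes: int
    trained: bool
    spontaneous_prob_per_bin: float | None = None


def _first_evoked_contact(
    licks: LickSeries,
    onset_ms: float,
    window_ms: float = EVOKED_WINDOW_MS,
):
    """First lick contact in the scoring window that belongs to a bout
    initiated at or after sound onset; returns (time, spout) or None."""
    starts = licks.bout_start_mask()
    times = licks.times_ms
    in_window = (times > onset_ms) & (times <= onset_ms + window_ms)
    for i in np.flatnonzero(in_window):
        # locate this contact's bout initiation
        j = i
        while j >= 0 and not starts[j]:
            j -= 1
        if times[j] >= onset_ms:
            return float(times[i]), str(licks.spouts[i])
        # the bout started pre-onset: subsequent contacts of the same
        # bout are not evoked; keep scanning for a fresh bout start
    return None


def _droplet_effective_trials(trials: list[Trial], licks: LickSeries, n_droplets: int) -> int:
    """Number of trials up to the consumption of the ``n_droplets``-th
    droplet.  A droplet pumped on trial i is consumed by the first lick
    after its pump and before the next pump replaces it."""
    times = licks.times_ms
    consumed = 0
    for i, trial in enumerate(trials):
        lo = trial.pump_onset_ms
        hi = trials[i + 1].pump_onset_ms if i + 1 < len(trials) else np.inf
        if np.any((times > lo) & (times <= hi)):
            consumed += 1
            if consumed >= n_droplets:
                return i + 1
    return len(trials)


def evoked_lick_probability(
    trials: list[Trial],
    licks: LickSeries,
    two_spout: bool = False,
    window_ms: float = EVOKED_WINDOW_MS,
    n_droplets: int = N_DROPLETS,
) -> SessionScore:
    """Session-level sound-evoked lick probability over effective trials.

    Success = first lick contact within ``window_ms`` of sound onset
    (and, for two-spout rigs, on the trial's assigned spout).  The
    denominator is truncated by the 20-droplet rule.
    """
    if not trials:
        raise ValueError("no trials")
    onsets = [t.onset_ms for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("trials must be sorted by onset")
    n_eff = _droplet_effective_trials(trials, licks, n_droplets)
    if n_eff == 0:
        raise ValueError("zero effective trials")
    successes = 0
    for trial in trials[:n_eff]:
        hit = _first_evoked_contact(licks, trial.onset_ms, window_ms)
        if hit is None:
            continue
        _, spout = hit
        if two_spout and spout != trial.spout:
            continue
        successes += 1
    p = successes / n_eff
    return SessionScore(
        evoked_lick_prob=p,
        n_effective_trials=n_eff,
        n_successes=successes,
        trained=p >= TRAINED_CRITERION,
    )


def spontaneous_lick_probability(
    trials: list[Trial],
    licks: LickSeries,
    bin_ms: float = 1000.0,
    tail_ms: float = 6000.0,
) -> float:
    """Probability of initiating a lick bout per inter-trial 1000 ms bin.

    Bins tile each inter-trial interval from the end of the post-stimulus
    scoring window to the next sound onset (the last trial is followed by
    a ``tail_ms`` grace interval).  A bout that began inside the scoring
    window and continues into the ITI contributes no initiation and is
    therefore not counted.
    """
    bout_starts = licks.bout_start_times()
    n_bins = 0
    n_hits = 0
    for i, trial in enumerate(trials):
        lo = trial.onset_ms + EVOKED_WINDOW_MS
        hi = trials[i + 1].onset_ms if i + 1 < len(trials) else trial.onset_ms + EVOKED_WINDOW_MS + tail_ms
        k = int((hi - lo) // bin_ms)
        if k < 1:
            continue
        n_bins += k
        for b in range(k):
            b_lo = lo + b * bin_ms
            if np.any((bout_starts >= b_lo) & (bout_starts < b_lo + bin_ms)):
                n_hits += 1
    if n_bins == 0:
        return 0.0
    return n_hits / n_bins


@dataclass
class SubsessionResult:
    per_bin: pd.DataFrame  # bin_index, trial_lo, trial_hi, lick_prob, burst_prob, partial
    grouped: pd.DataFrame  # range_lo, range_hi, lick_prob, burst_prob


def subsession_analysis(
    trials: list[Trial],
    licks: LickSeries,
    burst_flags,
    bin_size: int = 10,
    ranges: tuple = ((1, 20), (21, 50), (51, 80)),
    two_spout: bool = False,
) -> SubsessionResult:
    """Per-10-trial evoked-lick and bursting-response fractions.

    ``burst_flags`` aligns with ``trials`` and marks trials whose
    single-trial Δf/f reached the indicator burst threshold.  Droplet
    truncation is deliberately not applied here: the analysis tracks the
    motivational decay past satiation.  A final bin with fewer than
    ``bin_size`` trials is flagged partial.
    """
    burst_flags = np.asarray(burst_flags, dtype=bool)
    if burst_flags.size != len(trials):
        raise ValueError("burst_flags must align with trials")
    success = np.zeros(len(trials), dtype=bool)
    for i, trial in enumerate(trials):
        hit = _first_evoked_contact(licks, trial.onset_ms)
        if hit is None:
            continue
        _, spout = hit
        if two_spout and spout != trial.spout:
            continue
        success[i] = True

    rows = []
    for b, lo in enumerate(range(0, len(trials), bin_size)):
        hi = min(lo + bin_size, len(trials))
        rows.append(
            {
                "bin_index": b,
                "trial_lo": lo + 1,
                "trial_hi": hi,
                "lick_prob": float(success[lo:hi].mean()),
                "burst_prob": float(burst_flags[lo:hi].mean()),
                "partial": hi - lo < bin_size,
            }
        )
    per_bin = pd.DataFrame(rows)

    grows = []
    for lo, hi in ranges:
        sel = slice(lo - 1, min(hi, len(trials)))
        if sel.start >= len(trials):
            continue
        grows.append(
            {
                "range_lo": lo,
                "range_hi": hi,
                "lick_prob": float(success[sel].mean()),
                "burst_prob": float(burst_flags[sel].mean()),
            }
        )
    return SubsessionResult(per_bin=per_bin, grouped=pd.DataFrame(grows))
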