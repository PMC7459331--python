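"""Loose-patch electrophysiology: spikes, bursts and calibration.

A bursting response is a sound-triggered event of three or more spikes
within 150 ms of stimulus onset whose spike peak amplitudes decay over
the event.  This module detects spikes in voltage traces, applies the
burst rule per stimulus, summarises inter-spike-interval / timing
statistics, and tabulates the spike-count-to-Δf/f calibration used to
justify the imaging burst thresholds.

Conventions: the burst window is half-open, ``(onset, onset + 150 ms]``
(an onset-coincident spike is excluded); amplitude decay is fitted by
log-linear least squares ``A * exp(-(t - t1)/tau)`` and accepted when
the fitted tau is positive and the last peak is smaller than the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpikeTrain",
    "BurstEvent",
    "BurstTimingSummary",
    "BurstStats",
    "CalibrationTable",
    "detect_spikes",
    "detect_burst_events",
    "burst_statistics",
    "spike_dff_calibration",
]

BURST_WINDOW_MS = 150.0
BURST_MIN_SPIKES = 3


@dataclass
class SpikeTrain:
    """Spike times (ms) with positive peak amplitudes (trough depths)."""

    spike_times_ms: np.ndarray
    peak_amplitudes: np.ndarray
    sample_rate_hz: float = 20000.0

    def __post_init__(self) -> None:
        self.spike_times_ms = np.asarray(self.spike_times_ms, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.spike_times_ms.shape != self.peak_amplitudes.shape:
            raise ValueError("one amplitude per spike time required")
        if self.spike_times_ms.size > 1 and np.any(np.diff(self.spike_times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if np.any(self.peak_amplitudes <= 0):
            raise ValueError("peak amplitudes must be positive")


@dataclass(frozen=True)
class BurstEvent:
    onset_ms: float  # stimulus onset
    first_spike_ms: float
    last_spike_ms: float
    n_spikes: int
    decay_A: float
    decay_tau_ms: float
    decay_ok: bool
    spike_times_ms: tuple
    spike_amplitudes: tuple


@dataclass(frozen=True)
class BurstTimingSummary:
    """Median/IQR (ms, relative to stimulus onset) of burst onset, burst
    end, and lick onset."""

    burst_onset: tuple[float, float, float]
    burst_end: tuple[float, float, float]
    lick_onset: tuple[float, float, float] | None


@dataclass
class BurstStats:
    isis_ms: np.ndarray
    isi_hist: np.ndarray
    isi_bin_edges_ms: np.ndarray
    isi_median_iqr: tuple[float, float, float]
    rate_median_iqr_hz: tuple[float, float, float]
    timing: BurstTimingSummary


def detect_spikes(
    voltage: np.ndarray,
    sample_rate_hz: float = 20000.0,
    threshold_sd: float = 5.0,
    refractory_ms: float = 2.0,
) -> SpikeTrain:
    """Detect spikes as negative-going extrema in a loose-patch trace.

    The detection threshold is ``threshold_sd`` times a robust noise
    estimate (1.4826 x median absolute deviation).  Extrema closer than
    the refractory interval are merged, keeping the larger one.  A flat
    or sub-threshold trace yields an empty train.
    """
    v = np.asarray(voltage, dtype=float)
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if v.size < 0.1 * sample_rate_hz:
        raise ValueError("need at least 100 ms of voltage data")
    mad = np.median(np.abs(v - np.median(v)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        return SpikeTrain(np.empty(0), np.empty(0), sample_rate_hz)
    height = threshold_sd * noise_sd
    idx, props = find_peaks(-v, height=height)
    if idx.size == 0:
        return SpikeTrain(np.empty(0), np.empty(0), sample_rate_hz)
    amps = props["peak_heights"]
    # refractory merging: within refractory_ms keep the larger extremum
    min_gap = refractory_ms / 1000.0 * sample_rate_hz
    keep_idx: list[int] = []
    keep_amp: list[float] = []
    for i, a in zip(idx, amps):
        if keep_idx and i - keep_idx[-1] < min_gap:
            if a > keep_amp[-1]:
                keep_idx[-1] = int(i)
                keep_amp[-1] = float(a)
        else:
            keep_idx.append(int(i))
            keep_amp.append(float(a))
    times = np.array(keep_idx) / sample_rate_hz * 1000.0
    return SpikeTrain(times, np.array(keep_amp), sample_rate_hz)


def _fit_amplitude_decay(times_ms: np.ndarray, amps: np.ndarray) -> tuple[float, float, bool]:
    """Least-squares fit of log amplitudes vs time since the first spike.

    Returns (A, tau_ms, decay_ok).  The decay criterion requires a
    positive fitted tau (negative log-slope) and a last peak smaller
    than the first; a degenerate fit (equal amplitudes) fails it.
    """
    t = times_ms - times_ms[0]
    y = np.log(amps)
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0 or not np.isfinite(slope):
        return float(np.exp(intercept)), np.nan, False
    tau = -1.0 / slope
    ok = bool(amps[-1] < amps[0])
    return float(np.exp(intercept)), float(tau), ok


def detect_burst_events(
    train: SpikeTrain,
    stimulus_onsets_ms,
    window_ms: float = BURST_WINDOW_MS,
    min_spikes: int = BURST_MIN_SPIKES,
) -> list[BurstEvent]:
    """Apply the burst rule at each stimulus onset.

    A burst requires at least ``min_spikes`` spikes in the half-open
    window ``(onset, onset + window_ms]`` and a passing amplitude-decay
    fit over those spikes.
    """
    onsets = np.asarray(stimulus_onsets_ms, dtype=float)
    if onsets.size > 1 and np.any(np.diff(onsets) < 0):
        raise ValueError("stimulus onsets must be sorted")
    events: list[BurstEvent] = []
    for onset in onsets:
        mask = (train.spike_times_ms > onset) & (train.spike_times_ms <= onset + window_ms)
        if int(mask.sum()) < min_spikes:
            continue
        times = train.spike_times_ms[mask]
        amps = train.peak_amplitudes[mask]
        A, tau, ok = _fit_amplitude_decay(times, amps)
        if not ok:
            continue
        events.append(
            BurstEvent(
                onset_ms=float(onset),
                first_spike_ms=float(times[0]),
                last_spike_ms=float(times[-1]),
                n_spikes=int(times.size),
                decay_A=A,
                decay_tau_ms=tau,
                decay_ok=True,
                spike_times_ms=tuple(times),
                spike_amplitudes=tuple(amps),
            )
        )
    return events


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def burst_statistics(
    events: list[BurstEvent],
    lick_onsets_ms=None,
    isi_bin_width_ms: float = 2.0,
    isi_max_ms: float = 60.0,
) -> BurstStats:
    """Pool within-event ISIs, instantaneous rates and event timing.

    ``lick_onsets_ms`` are lick-bout onset latencies relative to
    stimulus onset (one per scored trial); burst onset/end are reported
    relative to each event's stimulus onset.
    """
    if not events:
        raise ValueError("need at least one burst event")
    isis = np.concatenate([np.diff(np.asarray(e.spike_times_ms)) for e in events])
    rates = 1000.0 / isis
    edges = np.arange(0.0, isi_max_ms + isi_bin_width_ms, isi_bin_width_ms)
    hist, _ = np.histogram(isis, bins=edges)
    onsets = np.array([e.first_spike_ms - e.onset_ms for e in events])
    ends = np.array([e.last_spike_ms - e.onset_ms for e in events])
    licks = None
    if lick_onsets_ms is not None and len(lick_onsets_ms) > 0:
        licks = _median_iqr(np.asarray(lick_onsets_ms, dtype=float))
    timing = BurstTimingSummary(
        burst_onset=_median_iqr(onsets),
        burst_end=_median_iqr(ends),
        lick_onset=licks,
    )
    return BurstStats(
        isis_ms=isis,
        isi_hist=hist,
        isi_bin_edges_ms=edges,
        isi_median_iqr=_median_iqr(isis),
        rate_median_iqr_hz=_median_iqr(rates),
        timing=timing,
    )


@dataclass
class CalibrationTable:
    """Per-spike-count Δf/f amplitude quartiles with the threshold check.

    ``min_count_above``: smallest spike count whose lower quartile
    exceeds the indicator threshold; ``max_count_below``: largest count
    whose upper quartile stays below it.  For a conservative threshold
    these bracket the 3-4 spike transition.
    """

    table: "pandas.DataFrame"
    threshold: float
    min_count_above: int | None
    max_count_below: int | None


def spike_dff_calibration(n_spikes, amplitudes, threshold: float) -> CalibrationTable:
    """Relate spikes per response event to single-trial Δf/f amplitude.

    ``n_spikes`` and ``amplitudes`` are paired arrays over response
    events.  Requires at least two distinct spike counts.
    """
    import pandas as pd

    n_spikes = np.asarray(n_spikes, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if n_spikes.shape != amplitudes.shape:
        raise ValueError("n_spikes and amplitudes must be paired")
    counts = np.unique(n_spikes)
    if counts.size < 2:
        raise ValueError("need at least two distinct spike counts")
    rows = []
    for c in counts:
        a = amplitudes[n_spikes == c]
        rows.append(
            {
                "n_spikes": int(c),
                "n_events": int(a.size),
                "q1": float(np.percentile(a, 25)),
                "median": float(np.median(a)),
                "q3": float(np.percentile(a, 75)),
            }
        )
    table = pd.DataFrame(rows)
    above = table[table["q1"] > threshold]["n_spikes"]
    below = table[table["q3"] < threshold]["n_spikes"]
    return CalibrationTable(
        table=table,
        threshold=threshold,
        min_count_above=int(above.min()) if len(above) else None,
        max_count_below=int(below.max()) if len(below) else None,
    )
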