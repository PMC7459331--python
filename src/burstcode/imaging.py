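"""Two-photon calcium-imaging quantification.

Turns movies and raw fluorescence traces into per-trial response
amplitudes: rigid motion correction by SSD minimisation, ROI trace
extraction, Δf/f normalisation against a percentile baseline, transient
detection, and single-trial / trial-averaged response amplitudes.

Conventions
-----------
* ``Δf/f = (f - f0) / f0`` with ``f0`` the 25th percentile of the entire
  recording (linear-interpolation percentile convention).
* Single-trial response amplitude = peak Δf/f in the 1000 ms window
  after stimulus onset minus the mean Δf/f in the 500 ms before onset.
  The 1000 ms window mirrors the behavioural scoring window; neither
  interval has a published definition, so both are configurable.
* Motion correction is integer-pixel rigid alignment only; each frame is
  shifted to minimise the mean squared intensity difference with the
  template (the average of the selected template frames) over the
  overlapping region, ties broken toward the smaller shift and then in
  row-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "TrialResponse",
    "TransientEvent",
    "MotionCorrection",
    "compute_dff",
    "correct_motion",
    "extract_traces",
    "detect_transients",
    "trial_response_amplitude",
    "trial_averaged",
    "response_table",
]


@dataclass
class FluorescenceTrace:
    """Raw fluorescence and its Δf/f normalisation for one ROI."""

    f: np.ndarray
    f0: float
    dff: np.ndarray
    frame_rate_hz: float
    indicator: str | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.f.shape != self.dff.shape:
            raise ValueError("f and dff must have equal length")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def n_frames(self) -> int:
        return self.f.size

    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate_hz


@dataclass(frozen=True)
class TrialResponse:
    cell_id: str
    trial_index: int
    stimulus_id: str
    amplitude: float
    window_ms: tuple[float, float] = (0.0, 1000.0)


@dataclass(frozen=True)
class TransientEvent:
    onset_frame: int
    peak_frame: int
    peak_amplitude: float
    max_rise_rate: float  # Δf/f per second


def compute_dff(
    f: np.ndarray,
    frame_rate_hz: float,
    indicator: str | None = None,
    baseline_percentile: float = 25.0,
) -> FluorescenceTrace:
    """Normalise a raw fluorescence trace to Δf/f.

    The baseline ``f0`` is the 25th percentile of the whole recording,
    computed with numpy's default linear interpolation between order
    statistics.  Raises ``ValueError`` for an empty trace or a
    non-positive baseline (degenerate recording).
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("empty fluorescence trace")
    f0 = float(np.percentile(f, baseline_percentile))
    if f0 <= 0:
        raise ValueError(f"degenerate baseline f0={f0!r} <= 0")
    dff = (f - f0) / f0
    return FluorescenceTrace(f=f, f0=f0, dff=dff, frame_rate_hz=frame_rate_hz, indicator=indicator)


# ---------------------------------------------------------------------------
# Motion correction


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D frame by whole pixels, zero-filling exposed borders."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def _overlap_ssd(frame: np.ndarray, template: np.ndarray, dy: int, dx: int) -> float:
    """Mean squared difference between the shifted frame and the template
    over the region where both are defined."""
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    a = frame[ys_src, xs_src].astype(float)
    b = template[ys, xs].astype(float)
    if a.size == 0:
        return np.inf
    d = a - b
    return float(np.mean(d * d))


@dataclass
class MotionCorrection:
    shifts: np.ndarray  # (n_frames, 2) applied corrections (dy, dx)
    aligned: np.ndarray  # corrected stack
    template: np.ndarray
    boundary_flags: np.ndarray  # True where the search grid was exhausted


def correct_motion(
    frames: np.ndarray,
    template_frames: np.ndarray | None = None,
    max_shift: int = 8,
) -> MotionCorrection:
    """Frame-by-frame rigid alignment minimising the sum of squared
    intensity differences against a template.

    Parameters
    ----------
    frames : (T, H, W) array.
    template_frames : frames averaged into the alignment template;
        defaults to the first 10 frames of the stack.
    max_shift : half-width of the integer search grid in pixels.

    Returns the per-frame applied correction (the inverse of the motion),
    the aligned stack, the template, and a per-frame flag set when the
    optimum lay on the search-grid boundary (possible under-correction).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (T, H, W) stack")
    if template_frames is None:
        template_frames = frames[:10]
    template_frames = np.asarray(template_frames)
    if template_frames.ndim != 3 or template_frames.shape[0] == 0:
        raise ValueError("need at least one template frame")
    if template_frames.shape[1:] != frames.shape[1:]:
        raise ValueError("template frames must match the stack shape")
    template = template_frames.astype(float).mean(axis=0)

    # Candidate order encodes the tie-break: smaller |shift| first,
    # then row-major (dy, dx).
    grid = [
        (dy, dx)
        for dy in range(-max_shift, max_shift + 1)
        for dx in range(-max_shift, max_shift + 1)
    ]
    grid.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))

    n = frames.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    flags = np.zeros(n, dtype=bool)
    aligned = np.empty_like(frames)
    for t in range(n):
        best = (0, 0)
        best_ssd = np.inf
        for dy, dx in grid:
            ssd = _overlap_ssd(frames[t], template, dy, dx)
            if ssd < best_ssd:
                best_ssd = ssd
                best = (dy, dx)
        shifts[t] = best
        if max(abs(best[0]), abs(best[1])) == max_shift:
            flags[t] = True
            warnings.warn(
                f"frame {t}: optimum shift {best} on the search boundary",
                RuntimeWarning,
                stacklevel=2,
            )
        aligned[t] = _translate(frames[t], *best)
    return MotionCorrection(shifts=shifts, aligned=aligned, template=template, boundary_flags=flags)


def extract_traces(frames: np.ndarray, roi_masks) -> np.ndarray:
    """Average pixel values inside each ROI mask, per frame.

    ``roi_masks`` is a sequence of boolean (H, W) arrays.  Returns an
    (n_roi, T) array of raw fluorescence.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (T, H, W)")
    out = np.empty((len(roi_masks), frames.shape[0]))
    for i, mask in enumerate(roi_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frames.shape[1:]:
            raise ValueError(f"mask {i} shape {mask.shape} does not match frames")
        if not mask.any():
            raise ValueError(f"mask {i} is empty")
        out[i] = frames[:, mask].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Transients and response amplitudes


def detect_transients(
    trace: FluorescenceTrace,
    amp_threshold: float = 0.3,
    rise_threshold: float = 2.0,
) -> list[TransientEvent]:
    """Detect calcium transients by joint peak-amplitude and rise-rate
    thresholding.

    An event is a contiguous run of samples at or above half the
    amplitude threshold that (a) contains a sample at or above
    ``amp_threshold`` and (b) reaches a maximum frame-to-frame rise rate
    of at least ``rise_threshold`` (Δf/f per second) during its rising
    phase.  Consecutive events are separated by a return below the
    half-threshold.
    """
    if amp_threshold <= 0 or rise_threshold <= 0:
        raise ValueError("thresholds must be positive")
    dff = trace.dff
    fr = trace.frame_rate_hz
    above_half = dff >= amp_threshold / 2.0
    events: list[TransientEvent] = []
    t = 0
    n = dff.size
    while t < n:
        if not above_half[t]:
            t += 1
            continue
        start = t
        while t < n and above_half[t]:
            t += 1
        end = t  # exclusive
        seg = dff[start:end]
        peak_rel = int(np.argmax(seg))
        peak_amp = float(seg[peak_rel])
        if peak_amp < amp_threshold:
            continue
        rising = seg[: peak_rel + 1]
        if rising.size < 2:
            # rise from below half-threshold into the first sample
            prev = dff[start - 1] if start > 0 else 0.0
            max_rise = (rising[0] - prev) * fr
        else:
            max_rise = float(np.max(np.diff(rising)) * fr)
        if max_rise >= rise_threshold:
            events.append(
                TransientEvent(
                    onset_frame=start,
                    peak_frame=start + peak_rel,
                    peak_amplitude=peak_amp,
                    max_rise_rate=float(max_rise),
                )
            )
    return events


def trial_response_amplitude(
    trace: FluorescenceTrace,
    trial,
    cell_id: str = "",
    response_window_ms: tuple[float, float] = (0.0, 1000.0),
    baseline_ms: float = 500.0,
) -> TrialResponse:
    """Single-trial response amplitude: peak Δf/f in the response window
    (relative to stimulus onset) minus the mean Δf/f in the pre-onset
    baseline interval.

    If the baseline interval extends before the recording start (first
    trial of a session), the available portion is used; with no frames at
    all the baseline is taken as zero.
    """
    onset = float(trial.onset_ms)
    times = trace.frame_times_ms()
    lo, hi = response_window_ms
    resp = trace.dff[(times > onset + lo) & (times <= onset + hi)]
    if resp.size == 0:
        raise ValueError("response window contains no frames")
    base = trace.dff[(times >= onset - baseline_ms) & (times < onset)]
    baseline = float(base.mean()) if base.size else 0.0
    amp = float(resp.max() - baseline)
    return TrialResponse(
        cell_id=cell_id,
        trial_index=int(trial.index),
        stimulus_id=str(trial.stimulus_id),
        amplitude=amp,
        window_ms=response_window_ms,
    )


def trial_averaged(amplitudes, min_trials: int = 3) -> float:
    """Trial-averaged response amplitude (arithmetic mean of single-trial
    amplitudes).  Requires at least ``min_trials`` trials."""
    amps = np.asarray(list(amplitudes), dtype=float)
    if amps.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {amps.size}")
    return float(amps.mean())


def response_table(traces: dict, trials) -> "pandas.DataFrame":
    """Single-trial response amplitudes for every cell x trial.

    ``traces`` maps cell_id -> FluorescenceTrace covering the session;
    ``trials`` is a list of Trial-like objects.  Returns a DataFrame with
    columns (cell_id, trial_index, stimulus_id, amplitude).
    """
    import pandas as pd

    rows = []
    for cell_id, trace in traces.items():
        times = trace.frame_times_ms()
        dff = trace.dff
        for trial in trials:
            onset = float(trial.onset_ms)
            resp = dff[(times > onset) & (times <= onset + 1000.0)]
            base = dff[(times >= onset - 500.0) & (times < onset)]
            baseline = float(base.mean()) if base.size else 0.0
            rows.append(
                (cell_id, int(trial.index), str(trial.stimulus_id), float(resp.max() - baseline))
            )
    return pd.DataFrame(rows, columns=["cell_id", "trial_index", "stimulus_id", "amplitude"])
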