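"""On-disk experiment bundles.

A synthetic experiment is persisted as one HDF5 file:

* ``/trials`` — trial table (index, stimulus, onset, pump, spout);
* ``/spikes/<cell>/<trial>`` — spike times (ms) and peak amplitudes;
* ``/traces/<cell>`` — raw fluorescence, float32, with ``frame_rate_hz``
  and ``indicator`` attributes;
* ``/licks`` — contact times and spout identity;
* ``/movie`` — optional uint16 stack with a ``planted_shifts`` attribute;

plus a ``*.ground_truth.json`` sidecar with the planted cell classes and
traits, so a reloaded bundle compares field-for-field equal.  Movies can
also be exported as multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from . import imaging
from .synthgen import (
    BehaviorModel,
    GroundTruthCell,
    IndicatorModel,
    LickSeries,
    SimSpikeTrain,
    SyntheticExperiment,
    Trial,
)

__all__ = ["save_experiment", "load_experiment", "export_movie_tiff"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".ground_truth.json")


def save_experiment(exp: SyntheticExperiment, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = exp.seed
        h5.attrs["fov_id"] = exp.fov_id
        tg = h5.create_group("trials")
        tg.create_dataset("index", data=np.array([t.index for t in exp.trials]))
        tg.create_dataset("onset_ms", data=np.array([t.onset_ms for t in exp.trials]))
        tg.create_dataset("pump_onset_ms", data=np.array([t.pump_onset_ms for t in exp.trials]))
        tg.create_dataset("sound_ms", data=np.array([t.sound_ms for t in exp.trials]))
        tg.create_dataset(
            "stimulus_id",
            data=np.array([t.stimulus_id for t in exp.trials], dtype=h5py.string_dtype()),
        )
        tg.create_dataset(
            "spout", data=np.array([t.spout for t in exp.trials], dtype=h5py.string_dtype())
        )
        sg = h5.create_group("spikes")
        for cell_id, per_trial in exp.spike_trains.items():
            cg = sg.create_group(cell_id)
            for trial_idx, tr in per_trial.items():
                g = cg.create_group(str(trial_idx))
                g.create_dataset("times_ms", data=tr.times_ms)
                g.create_dataset("amplitudes", data=tr.amplitudes)
                g.attrs["is_burst"] = bool(tr.is_burst)
                g.attrs["n_spikes"] = int(tr.n_spikes)
        rg = h5.create_group("traces")
        for cell_id, trace in exp.traces.items():
            d = rg.create_dataset(cell_id, data=trace.f.astype(np.float32))
            d.attrs["frame_rate_hz"] = trace.frame_rate_hz
            d.attrs["indicator"] = trace.indicator or ""
        lg = h5.create_group("licks")
        lg.create_dataset("time_ms", data=exp.licks.times_ms)
        lg.create_dataset(
            "spout", data=np.array(list(exp.licks.spouts), dtype=h5py.string_dtype())
        )
        if exp.movie is not None:
            d = h5.create_dataset("movie", data=exp.movie)
            d.attrs["planted_shifts"] = exp.planted_shifts

    gt = {
        "seed": exp.seed,
        "indicator": {
            "indicator": exp.indicator.indicator,
            "unit_amp": exp.indicator.unit_amp,
            "tau_rise_ms": exp.indicator.tau_rise_ms,
            "tau_decay_ms": exp.indicator.tau_decay_ms,
            "noise_sd": exp.indicator.noise_sd,
            "frame_rate_hz": exp.indicator.frame_rate_hz,
            "f_baseline": exp.indicator.f_baseline,
        },
        "behavior": {
            "p_early": exp.behavior.p_early,
            "p_late": exp.behavior.p_late,
            "decay_center_trial": exp.behavior.decay_center_trial,
            "decay_scale_trials": exp.behavior.decay_scale_trials,
            "spontaneous_rate": exp.behavior.spontaneous_rate,
            "spout_error_prob": exp.behavior.spout_error_prob,
        },
        "cells": [
            {
                "cell_id": c.cell_id,
                "true_class": c.true_class,
                "chord_index": c.chord_index,
                "preferred_stimuli": sorted(c.preferred_stimuli),
                "burst_prob": c.burst_prob,
                "burst_amp": dict(sorted(c.burst_amp.items())),
                "baseline_amp": dict(sorted(c.baseline_amp.items())),
            }
            for c in exp.cells
        ],
    }
    _sidecar(path).write_text(json.dumps(gt, indent=1, sort_keys=True))
    return path


def load_experiment(path) -> SyntheticExperiment:
    path = Path(path)
    gt = json.loads(_sidecar(path).read_text())
    ind = IndicatorModel(**gt["indicator"])
    cells = [
        GroundTruthCell(
            cell_id=c["cell_id"],
            true_class=c["true_class"],
            chord_index=c["chord_index"],
            preferred_stimuli=frozenset(c["preferred_stimuli"]),
            burst_prob=c["burst_prob"],
            burst_amp=c["burst_amp"],
            baseline_amp=c["baseline_amp"],
        )
        for c in gt["cells"]
    ]
    with h5py.File(path, "r") as h5:
        tg = h5["trials"]
        trials = [
            Trial(
                index=int(i),
                stimulus_id=s.decode() if isinstance(s, bytes) else str(s),
                onset_ms=float(o),
                sound_ms=float(sm),
                pump_onset_ms=float(p),
                spout=sp.decode() if isinstance(sp, bytes) else str(sp),
            )
            for i, s, o, sm, p, sp in zip(
                tg["index"][()],
                tg["stimulus_id"][()],
                tg["onset_ms"][()],
                tg["sound_ms"][()],
                tg["pump_onset_ms"][()],
                tg["spout"][()],
            )
        ]
        spike_trains = {}
        for cell_id, cg in h5["spikes"].items():
            spike_trains[cell_id] = {
                int(k): SimSpikeTrain(
                    times_ms=g["times_ms"][()],
                    amplitudes=g["amplitudes"][()],
                    is_burst=bool(g.attrs["is_burst"]),
                    n_spikes=int(g.attrs["n_spikes"]),
                )
                for k, g in cg.items()
            }
        traces = {}
        for cell_id, d in h5["traces"].items():
            ind_name = d.attrs["indicator"] or None
            traces[cell_id] = imaging.compute_dff(
                d[()].astype(float), float(d.attrs["frame_rate_hz"]), indicator=ind_name
            )
        licks = LickSeries(
            times_ms=h5["licks/time_ms"][()],
            spouts=np.array(
                [s.decode() if isinstance(s, bytes) else str(s) for s in h5["licks/spout"][()]],
                dtype=object,
            ),
        )
        movie = shifts = None
        if "movie" in h5:
            movie = h5["movie"][()]
            shifts = np.asarray(h5["movie"].attrs["planted_shifts"])
        seed = int(h5.attrs["seed"])
        fov_id = str(h5.attrs["fov_id"])
    return SyntheticExperiment(
        trials=trials,
        cells=cells,
        spike_trains=spike_trains,
        traces=traces,
        licks=licks,
        indicator=ind,
        behavior=BehaviorModel(**gt.get("behavior", {})),
        seed=seed,
        movie=movie,
        planted_shifts=shifts,
        fov_id=fov_id,
    )


def export_movie_tiff(exp: SyntheticExperiment, path) -> Path:
    import tifffile

    if exp.movie is None:
        raise ValueError("experiment has no movie")
    path = Path(path)
    tifffile.imwrite(path, exp.movie)
    return path
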