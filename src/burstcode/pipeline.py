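"""End-to-end scenario runs: simulate -> process -> classify -> decode.

A scenario bundles the study conditions of one analysis: the training
paradigm, the planted population composition, the indicator, and the
report set.  Built-in scenarios:

* ``bbn_single_mouse`` — one field of view from a broadband-noise
  trained animal (32 non-bursting + 3 holistic cells);
* ``bbn_hypermouse`` — 681 cells across 22 FOVs (614 NB / 37 AB /
  8 qHB / 22 HB), tone battery + noise, decoding curves;
* ``chord_hypermouse`` — 570 cells across 19 FOVs with the six-subtype
  split (528 NB / 19 AB / 2 qHB-c1 / 3 HB-c1 / 3 qHB-c2 / 15 HB-c2);
* ``trained_cal520`` — the pooled trained-stage population (1112 cells,
  52 bursting) tested with the trained sound only;
* ``naive_control`` — the pooled naive population (1314 cells, 2
  bursting).

Everything is deterministic under the scenario seed; per-stage seeds
derive from it through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import imaging
from .cellclass import StimulusStructure, classify_population, is_bursting_responsive
from .decode import ResponseMatrix, make_hypermouse, recruitment_curve
from .popstats import bursting_fraction, fit_lognormal
from .synthgen import (
    BehaviorModel,
    ProtocolConfig,
    Stimulus,
    TEST_TONES,
    default_indicator,
    default_stimulus_set,
    make_population,
    simulate_experiment,
)

__all__ = [
    "ScenarioConfig",
    "SchemaError",
    "SCENARIOS",
    "run_scenario",
    "write_report",
    "simulate_cohort",
    "motivation_analysis",
]

TRIALS_PER_STIMULUS = 9

SCENARIOS: dict[str, dict] = {
    "bbn_single_mouse": {
        "paradigm": "BBN",
        "indicator": "Cal520",
        "composition": {"NB": 32, "HB": 3},
        "n_fov": 1,
        "target_stimulus": "BBN",
        "classify": True,
        "decode": True,
    },
    "bbn_hypermouse": {
        "paradigm": "BBN",
        "indicator": "Cal520",
        "composition": {"NB": 614, "AB": 37, "qHB": 8, "HB": 22},
        "n_fov": 22,
        "target_stimulus": "BBN",
        "classify": True,
        "decode": True,
    },
    "chord_hypermouse": {
        "paradigm": "two_chord",
        "indicator": "Cal520",
        "composition": {
            "NB": 528, "AB": 19,
            "qHB_c1": 2, "HB_c1": 3, "qHB_c2": 3, "HB_c2": 15,
        },
        "n_fov": 19,
        "target_stimulus": "chord2",
        "classify": True,
        "decode": True,
    },
    "trained_cal520": {
        "paradigm": "BBN",
        "indicator": "Cal520",
        "composition": {"NB": 1060, "HB": 52},
        "n_fov": 18,
        "target_stimulus": "BBN",
        "trained_sound_only": True,
        "classify": False,
        "decode": False,
    },
    "naive_control": {
        "paradigm": "BBN",
        "indicator": "Cal520",
        "composition": {"NB": 1312, "HB": 2},
        "n_fov": 8,
        "target_stimulus": "BBN",
        "trained_sound_only": True,
        "classify": False,
        "decode": False,
        "naive_behavior": True,
    },
}


@dataclass
class ScenarioConfig:
    scenario: str
    seed: int = 0
    output_dir: str | None = None
    overrides: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        cfg = dict(SCENARIOS[self.scenario])
        cfg.update(self.overrides)
        return cfg


class SchemaError(ValueError):
    """The report bundle violates its schema."""


def _label_key(row) -> str:
    if row.chord_index is not None and not (isinstance(row.chord_index, float) and np.isnan(row.chord_index)):
        return f"{row.label}_c{int(row.chord_index)}"
    return str(row.label)


def simulate_cohort(
    composition: dict,
    paradigm: str,
    indicator: str,
    n_fov: int,
    seed: int,
    trials_per_stimulus: int = TRIALS_PER_STIMULUS,
    stimulus_set: list[Stimulus] | None = None,
    behavior_model: BehaviorModel | None = None,
):
    """Simulate a multi-FOV cohort and return (responses, fov_tables,
    behavior_rows).

    The population is planted once and dealt round-robin into FOVs; each
    FOV is an independent session (own randomized trial order and its
    own noise), as when pooling animals into a hypermouse.  Returns the
    pooled single-trial response table, per-FOV (responses, labels-free)
    tables for decoding, and per-FOV behaviour scores.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, *fov_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_fov + 1)]
    stimulus_set = stimulus_set or default_stimulus_set(paradigm)
    cells = make_population(composition, paradigm=paradigm, seed=pop_seed,
                            stimulus_set=default_stimulus_set(paradigm), indicator=indicator)
    rng = np.random.default_rng(pop_seed)
    order = rng.permutation(len(cells))
    fov_assignment = [order[i::n_fov] for i in range(n_fov)]

    ind = default_indicator(indicator)
    n_trials = trials_per_stimulus * len(stimulus_set)
    fov_tables = []
    behavior_rows = []
    all_responses = []
    for f, idx in enumerate(fov_assignment):
        if idx.size == 0:
            continue
        fov_cells = [cells[i] for i in idx]
        protocol = ProtocolConfig(
            paradigm=paradigm,
            stimulus_set=stimulus_set,
            n_trials=n_trials,
            seed=fov_seeds[f],
            start_ms=2000.0,
        )
        exp = simulate_experiment(
            protocol, fov_cells, indicator=ind,
            behavior=behavior_model, seed=fov_seeds[f] + 1, fov_id=f"fov{f:02d}",
        )
        resp = imaging.response_table(exp.traces, exp.trials)
        resp["fov_id"] = exp.fov_id
        all_responses.append(resp)
        fov_tables.append((exp.fov_id, resp, exp.trials))
        score = behavior_mod.evoked_lick_probability(exp.trials, exp.licks)
        spont = behavior_mod.spontaneous_lick_probability(exp.trials, exp.licks)
        behavior_rows.append(
            {
                "fov_id": exp.fov_id,
                "evoked_lick_prob": score.evoked_lick_prob,
                "n_effective_trials": score.n_effective_trials,
                "trained": score.trained,
                "spontaneous_prob_per_bin": spont,
            }
        )
    responses = pd.concat(all_responses, ignore_index=True)
    return cells, responses, fov_tables, behavior_rows


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one scenario end to end and return the report dict.

    Produces, when ``config.output_dir`` is set: ``report.json``,
    ``responses.csv``, ``cell_labels.csv``, ``behavior.csv`` and
    ``recruitment_curve.csv``.
    """
    cfg = config.resolved()
    paradigm = cfg["paradigm"]
    indicator = cfg["indicator"]
    target = cfg["target_stimulus"]
    full_set = default_stimulus_set(paradigm)
    stimulus_set = full_set
    if cfg.get("trained_sound_only"):
        stimulus_set = [s for s in full_set if s.stim_id == target]
    behavior_model = BehaviorModel()
    if cfg.get("naive_behavior"):
        # naive animals lick rarely and independently of the sound
        behavior_model = BehaviorModel(p_early=0.05, p_late=0.03, decay_center_trial=10.0)

    try:
        cells, responses, fov_tables, behavior_rows = simulate_cohort(
            cfg["composition"], paradigm, indicator, cfg["n_fov"], config.seed,
            stimulus_set=stimulus_set, behavior_model=behavior_model,
        )
        trial_avg = (
            responses.groupby(["cell_id", "stimulus_id"], as_index=False)["amplitude"].mean()
        )

        report: dict = {
            "scenario": config.scenario,
            "seed": config.seed,
            "n_cells": int(responses["cell_id"].nunique()),
            "n_fov": len(fov_tables),
            "paradigm": paradigm,
            "indicator": indicator,
        }

        labels_df = None
        if cfg.get("classify", True):
            structure = StimulusStructure(full_set)
            labels_df = classify_population(trial_avg, structure, indicator)
            keys = labels_df.apply(_label_key, axis=1)
            wanted = (
                ["NB", "AB", "qHB_c1", "HB_c1", "qHB_c2", "HB_c2"]
                if paradigm == "two_chord"
                else ["NB", "AB", "qHB", "HB"]
            )
            report["label_counts"] = {k: int((keys == k).sum()) for k in wanted}
            flags = (labels_df["label"] != "NB").to_numpy()
        else:
            tgt = trial_avg[trial_avg["stimulus_id"] == target]
            flags = np.array(
                [is_bursting_responsive(a, indicator) for a in tgt["amplitude"]]
            )
            report["label_counts"] = {
                "bursting": int(flags.sum()),
                "NB": int((~flags).sum()),
            }
        frac, n_b, n_tot = bursting_fraction(flags)
        report["bursting_fraction"] = {
            "fraction": frac, "n_bursting": n_b, "n_total": n_tot,
        }

        tgt_amp = trial_avg[trial_avg["stimulus_id"] == target]["amplitude"].to_numpy()
        if (tgt_amp > 0).sum() >= 10:
            fit = fit_lognormal(tgt_amp)
            report["lognormal_fit"] = {
                "mu_log": fit.mu_log, "sigma_log": fit.sigma_log,
                "n": fit.n, "n_excluded": fit.n_excluded, "ks_stat": fit.ks_stat,
            }
        else:  # population too small for a meaningful fit
            report["lognormal_fit"] = None

        report["behavior"] = {
            "per_fov": behavior_rows,
            "mean_evoked_lick_prob": float(
                np.mean([r["evoked_lick_prob"] for r in behavior_rows])
            ),
            "mean_spontaneous_prob": float(
                np.mean([r["spontaneous_prob_per_bin"] for r in behavior_rows])
            ),
        }

        report["recruitment"] = {}
        if cfg.get("decode", False):
            label_keys = labels_df.set_index("cell_id").apply(_label_key, axis=1)
            mats = []
            for fov_id, resp, _trials in fov_tables:
                m = ResponseMatrix.from_responses(
                    resp.drop(columns=["fov_id"]), target, fov_id=fov_id
                )
                m.cell_labels = [str(label_keys[c]) for c in m.cell_ids]
                mats.append(m)
            hyper = make_hypermouse(mats) if len(mats) > 1 else mats[0]
            if paradigm == "two_chord":
                policies = {
                    "nb_first": ["NB", "AB", "qHB_c1", "HB_c1", "qHB_c2", "HB_c2"],
                    "bursting_first": ["HB_c2", "qHB_c2", "HB_c1", "qHB_c1", "AB", "NB"],
                }
            else:
                policies = {
                    "nb_first": ["NB", "AB", "qHB", "HB"],
                    "bursting_first": ["HB", "qHB", "AB", "NB"],
                }
            lab_arr = np.array(hyper.cell_labels)
            ss = np.random.SeedSequence([config.seed, 77])
            for name, policy in policies.items():
                groups = {g: np.flatnonzero(lab_arr == g) for g in policy}
                groups = {g: v for g, v in groups.items()}
                rng = np.random.default_rng(ss.spawn(1)[0])
                res = recruitment_curve(hyper, policy=[g for g in policy], rng=rng, groups=groups)
                report["recruitment"][name] = {
                    "policy": res.policy,
                    "group_boundaries": res.group_boundaries,
                    "n_p": res.n_p.tolist(),
                    "mean_ac": [round(float(v), 6) for v in res.mean_ac],
                    "sd_ac": [round(float(v), 6) for v in res.sd_ac],
                }
    except (ValueError, KeyError) as e:
        raise RuntimeError(f"scenario stage failed: {e}") from e

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        responses.to_csv(out / "responses.csv", index=False)
        if labels_df is not None:
            labels_df.to_csv(out / "cell_labels.csv", index=False)
        pd.DataFrame(behavior_rows).to_csv(out / "behavior.csv", index=False)
        rows = []
        for name, r in report["recruitment"].items():
            for npv, m, s in zip(r["n_p"], r["mean_ac"], r["sd_ac"]):
                rows.append({"policy": name, "n_p": npv, "mean_ac": m, "sd_ac": s})
        pd.DataFrame(rows, columns=["policy", "n_p", "mean_ac", "sd_ac"]).to_csv(
            out / "recruitment_curve.csv", index=False
        )
        write_report(report, out / "report.json")
    else:
        validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Schema check for the report bundle."""
    required = [
        "scenario", "seed", "n_cells", "label_counts",
        "bursting_fraction", "behavior", "recruitment", "lognormal_fit",
    ]
    for key in required:
        if key not in report:
            raise SchemaError(f"report missing {key!r}")
    bf = report["bursting_fraction"]
    for key in ("fraction", "n_bursting", "n_total"):
        if key not in bf:
            raise SchemaError(f"bursting_fraction missing {key!r}")
    if not isinstance(report["label_counts"], dict) or not report["label_counts"]:
        raise SchemaError("label_counts must be a non-empty mapping")
    for name, r in report["recruitment"].items():
        for key in ("n_p", "mean_ac", "sd_ac"):
            if key not in r:
                raise SchemaError(f"recruitment[{name!r}] missing {key!r}")
        if not (len(r["n_p"]) == len(r["mean_ac"]) == len(r["sd_ac"])):
            raise SchemaError(f"recruitment[{name!r}] length mismatch")


def write_report(report: dict, path) -> Path:
    """Validate and serialise the report; round-trips unchanged."""
    validate_report(report)
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Motivation-vs-burst dissociation


def motivation_analysis(
    n_replicates: int = 50,
    n_trials: int = 80,
    seed: int = 0,
    indicator: str = "Cal520",
    burst_prob: float | None = None,
) -> dict:
    """Burst reliability versus motivational decay over long sessions.

    Simulates ``n_replicates`` single-cell sessions of ``n_trials``
    trained-sound trials under the default satiation schedule, scores
    per-10-trial subsessions, and aggregates across replicates.
    Returns per-bin mean lick/burst fractions, their minimum across
    bins, and the late-range (trials 51-80) mean lick probability.
    """
    ss = np.random.SeedSequence([seed, 505])
    ind = default_indicator(indicator)
    threshold = ind.threshold
    stimulus_set = [Stimulus("BBN", components=TEST_TONES, spout="single")]
    lick_bins = []
    burst_bins = []
    late_lick = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        comp = {"HB": 1}
        cells = make_population(comp, paradigm="BBN", seed=rep_seed, indicator=indicator)
        if burst_prob is not None:
            cells[0].burst_prob = burst_prob
        protocol = ProtocolConfig(
            paradigm="BBN", stimulus_set=stimulus_set, n_trials=n_trials,
            seed=rep_seed + 1, start_ms=2000.0,
        )
        exp = simulate_experiment(protocol, cells, indicator=ind, seed=rep_seed + 2)
        resp = imaging.response_table(exp.traces, exp.trials)
        flags = resp.sort_values("trial_index")["amplitude"].to_numpy() >= threshold
        result = behavior_mod.subsession_analysis(exp.trials, exp.licks, flags)
        lick_bins.append(result.per_bin["lick_prob"].to_numpy())
        burst_bins.append(result.per_bin["burst_prob"].to_numpy())
        late = result.grouped[result.grouped["range_lo"] == 51]
        late_lick.append(float(late["lick_prob"].iloc[0]))
    lick_bins = np.vstack(lick_bins)
    burst_bins = np.vstack(burst_bins)
    return {
        "n_replicates": n_replicates,
        "mean_lick_per_bin": lick_bins.mean(axis=0).tolist(),
        "mean_burst_per_bin": burst_bins.mean(axis=0).tolist(),
        "min_mean_burst_per_bin": float(burst_bins.mean(axis=0).min()),
        "late_lick_prob": float(np.mean(late_lick)),
    }
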