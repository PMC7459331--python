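"""One-shot linear population decoding and recruitment curves.

The decoding protocol trains a two-class linear maximum-margin
classifier on a single randomly chosen trial per class and tests it on
one different randomly chosen trial per class; with one training point
per class the maximum-margin separator is exactly the perpendicular
bisector of the two points, so classification reduces to
nearest-of-the-two-training-points.  Accuracy A_c at each population
size N_p is averaged over 50 random cell selections x 50 random
training/testing trial draws, the classifier being discarded between
draws.  Cells are recruited in policy order (e.g. non-bursting cells
first, or bursting cells first); the classifier itself never sees the
cell labels — only the recruitment schedule uses them.

A *hypermouse* concatenates cells across imaged fields of view,
merging for each stimulus the k-th chronological trial of every FOV
into one virtual trial (truncated to the smallest per-stimulus trial
count across FOVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "DecodingResult",
    "make_hypermouse",
    "one_shot_accuracy",
    "recruitment_curve",
]


@dataclass
class ResponseMatrix:
    """Single-trial Δf/f responses, trials x cells, with class labels.

    ``y`` is True for target-class trials.  ``cell_labels`` (optional)
    carries the NB/AB/qHB/HB taxonomy for recruitment policies;
    ``stimulus_ids`` and ``chron_index`` record, per trial, the stimulus
    and its within-stimulus chronological order (used for hypermouse
    alignment).
    """

    X: np.ndarray
    y: np.ndarray
    cell_ids: list
    stimulus_ids: list = field(default_factory=list)
    chron_index: np.ndarray | None = None
    cell_labels: list | None = None
    fov_ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_trials, n_cells) aligned with y")
        if not np.isfinite(self.X).all():
            raise ValueError("response matrix contains missing entries")
        if self.y.sum() < 2 or (~self.y).sum() < 2:
            raise ValueError("need at least 2 trials per class")

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_responses(
        cls,
        responses: pd.DataFrame,
        target_stimulus: str,
        cell_labels: pd.DataFrame | None = None,
        fov_id: str | None = None,
    ) -> "ResponseMatrix":
        """Build from a (cell_id, trial_index, stimulus_id, amplitude)
        table; trials become rows, cells columns, target = trials of
        ``target_stimulus``."""
        wide = responses.pivot(index="trial_index", columns="cell_id", values="amplitude")
        if wide.isna().any().any():
            raise ValueError("missing cell x trial entries")
        stim = (
            responses[["trial_index", "stimulus_id"]]
            .drop_duplicates()
            .set_index("trial_index")["stimulus_id"]
            .reindex(wide.index)
        )
        # per-stimulus chronological order (trial_index is chronological)
        chron = stim.to_frame().groupby("stimulus_id").cumcount().to_numpy()
        labels = None
        if cell_labels is not None:
            lab = cell_labels.set_index("cell_id")["label"]
            labels = [str(lab[c]) for c in wide.columns]
        return cls(
            X=wide.to_numpy(),
            y=(stim == target_stimulus).to_numpy(),
            cell_ids=list(wide.columns),
            stimulus_ids=list(stim),
            chron_index=chron,
            cell_labels=labels,
            fov_ids=[fov_id] * wide.shape[1] if fov_id else None,
        )


def make_hypermouse(matrices: list[ResponseMatrix]) -> ResponseMatrix:
    """Concatenate FOVs into one virtual animal.

    All FOVs must share the stimulus set.  For each stimulus, the k-th
    chronological trial of every FOV is merged into one hyper-trial;
    the per-stimulus trial count is truncated to the minimum across
    FOVs.  Cell order follows FOV order (a permutation of FOVs permutes
    columns only).
    """
    if not matrices:
        raise ValueError("no matrices")
    stim_sets = [set(m.stimulus_ids) for m in matrices]
    common = set.intersection(*stim_sets)
    if any(s != stim_sets[0] for s in stim_sets) or not common:
        raise ValueError("all FOVs must share the same stimulus set")
    stimuli = sorted(common)

    blocks = []
    y_out: list[bool] = []
    stim_out: list[str] = []
    chron_out: list[int] = []
    for stim in stimuli:
        n_min = min(int(np.sum(np.array(m.stimulus_ids) == stim)) for m in matrices)
        for k in range(n_min):
            row_parts = []
            y_val = None
            for m in matrices:
                idx = np.flatnonzero((np.array(m.stimulus_ids) == stim) & (m.chron_index == k))
                row_parts.append(m.X[idx[0]])
                y_val = bool(m.y[idx[0]])
            blocks.append(np.concatenate(row_parts))
            y_out.append(y_val)
            stim_out.append(stim)
            chron_out.append(k)

    labels = None
    if all(m.cell_labels is not None for m in matrices):
        labels = sum((list(m.cell_labels) for m in matrices), [])
    fovs = None
    if all(m.fov_ids is not None for m in matrices):
        fovs = sum((list(m.fov_ids) for m in matrices), [])
    return ResponseMatrix(
        X=np.vstack(blocks),
        y=np.array(y_out),
        cell_ids=sum((list(m.cell_ids) for m in matrices), []),
        stimulus_ids=stim_out,
        chron_index=np.array(chron_out),
        cell_labels=labels,
        fov_ids=fovs,
    )


# ---------------------------------------------------------------------------
# One-shot decoding


def _draw_pairs(rng: np.random.Generator, idx_t: np.ndarray, idx_n: np.ndarray, n_draws: int):
    """Per draw: (train_target, train_nontarget, test_target,
    test_nontarget) trial indices, with train != test within a class."""
    tr_t = idx_t[rng.integers(0, idx_t.size, size=n_draws)]
    tr_n = idx_n[rng.integers(0, idx_n.size, size=n_draws)]
    te_t = np.empty(n_draws, dtype=int)
    te_n = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        while True:
            c = idx_t[rng.integers(0, idx_t.size)]
            if c != tr_t[d]:
                te_t[d] = c
                break
        while True:
            c = idx_n[rng.integers(0, idx_n.size)]
            if c != tr_n[d]:
                te_n[d] = c
                break
    return tr_t, tr_n, te_t, te_n


def _score(s_target: np.ndarray, s_nontarget: np.ndarray) -> np.ndarray:
    """Per-draw accuracy over the 2 test trials given signed margins
    (positive = classified target).  A zero margin (coincident training
    points) counts half."""
    acc_t = np.where(s_target > 0, 1.0, np.where(s_target == 0, 0.5, 0.0))
    acc_n = np.where(s_nontarget < 0, 1.0, np.where(s_nontarget == 0, 0.5, 0.0))
    return (acc_t + acc_n) / 2.0


def one_shot_accuracy(
    matrix: ResponseMatrix,
    cell_subset=None,
    rng: np.random.Generator | None = None,
    n_draws: int = 50,
) -> float:
    """Mean one-shot accuracy over ``n_draws`` training/testing draws.

    Each draw trains the maximum-margin linear classifier on one random
    trial per class and scores one different random trial per class
    (per-draw accuracy in {0, 0.5, 1}); classifier state is discarded
    between draws.
    """
    rng = rng or np.random.default_rng()
    subset = np.arange(matrix.n_cells) if cell_subset is None else np.asarray(cell_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("cell subset must be non-empty")
    idx_t = np.flatnonzero(matrix.y)
    idx_n = np.flatnonzero(~matrix.y)
    if idx_t.size < 2 or idx_n.size < 2:
        raise ValueError("need at least 2 trials per class")
    X = matrix.X[:, subset]
    tr_t, tr_n, te_t, te_n = _draw_pairs(rng, idx_t, idx_n, n_draws)
    w = X[tr_t] - X[tr_n]  # (draws, cells)
    mid = (X[tr_t] + X[tr_n]) / 2.0
    s_t = np.einsum("dc,dc->d", X[te_t] - mid, w)
    s_n = np.einsum("dc,dc->d", X[te_n] - mid, w)
    return float(_score(s_t, s_n).mean())


@dataclass
class DecodingResult:
    policy: list
    n_p: np.ndarray
    mean_ac: np.ndarray
    sd_ac: np.ndarray
    group_boundaries: dict  # group name -> last N_p of the group
    n_cell_draws: int = 50
    n_trial_draws: int = 50

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_p": self.n_p, "mean_ac": self.mean_ac, "sd_ac": self.sd_ac}
        )


def recruitment_curve(
    matrix: ResponseMatrix,
    policy: list,
    rng: np.random.Generator | None = None,
    n_selections: int = 50,
    n_draws: int = 50,
    groups: dict | None = None,
) -> DecodingResult:
    """Accuracy versus population size under a recruitment policy.

    ``policy`` is an ordered list of label-group names; earlier groups
    are exhausted before later ones, and the partially-used group is a
    uniformly random subset, resampled per cell selection.  ``groups``
    may map group name -> cell index array explicitly; otherwise groups
    are taken from ``matrix.cell_labels``.  For every N_p from 1 to the
    total cell count, the mean and s.d. of A_c across ``n_selections``
    cell selections are reported (each selection averaging ``n_draws``
    one-shot train/test draws).

    Internally each selection is one random within-group permutation
    whose prefixes realise the recruited set at every N_p, so the whole
    curve is computed from cumulative dot products in a single pass.
    """
    rng = rng or np.random.default_rng()
    if groups is None:
        if matrix.cell_labels is None:
            raise ValueError("matrix has no cell labels; pass explicit groups")
        lab = np.array([str(l) for l in matrix.cell_labels])
        groups = {g: np.flatnonzero(lab == g) for g in policy}
    covered = np.concatenate([np.asarray(groups[g], dtype=int) for g in policy]) if policy else np.empty(0, int)
    if len(set(covered.tolist())) != matrix.n_cells or covered.size != matrix.n_cells:
        raise ValueError("policy groups must partition the cells")

    idx_t = np.flatnonzero(matrix.y)
    idx_n = np.flatnonzero(~matrix.y)
    if idx_t.size < 2 or idx_n.size < 2:
        raise ValueError("need at least 2 trials per class")
    X = matrix.X
    n_cells = matrix.n_cells

    acc = np.empty((n_selections, n_cells))
    for s in range(n_selections):
        order = np.concatenate(
            [rng.permutation(np.asarray(groups[g], dtype=int)) for g in policy]
        )
        tr_t, tr_n, te_t, te_n = _draw_pairs(rng, idx_t, idx_n, n_draws)
        w = (X[tr_t] - X[tr_n])[:, order]  # (draws, ordered cells)
        mid = ((X[tr_t] + X[tr_n]) / 2.0)[:, order]
        a = np.cumsum((X[te_t][:, order] - mid) * w, axis=1)
        b = np.cumsum((X[te_n][:, order] - mid) * w, axis=1)
        acc[s] = _score(a, b).mean(axis=0)

    boundaries = {}
    total = 0
    for g in policy:
        total += len(groups[g])
        boundaries[g] = total
    return DecodingResult(
        policy=list(policy),
        n_p=np.arange(1, n_cells + 1),
        mean_ac=acc.mean(axis=0),
        sd_ac=acc.std(axis=0, ddof=0),
        group_boundaries=boundaries,
        n_cell_draws=n_selections,
        n_trial_draws=n_draws,
    )
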