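"""Beta-series functional connectivity between ROI pairs.

Per-trial voxelwise t-statistics are averaged over each ROI's voxels to
give one scalar per trial; trials are binned by (total changes, task)
into ten beta-series per ROI; Pearson correlations between matching bins
of two ROIs are Fisher-transformed (z = atanh r) and tabulated per
participant, pair, task and changes level.  Averaging across tasks is
done on the z scale (variance-stabilized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import Trial, TrialSchedule
from .glm import TrialEstimates

#: tidy table columns for connectivity output
TABLE_COLUMNS = ["participant", "hemisphere", "pair", "task",
                 "total_changes", "n_trials", "r", "z"]


class ConstantSeriesError(ValueError):
    pass


class PerfectCorrelationError(ValueError):
    pass


@dataclass
class BetaSeries:
    """Ordered per-trial scalar estimates for one ROI and one condition."""

    roi_name: str
    total_changes: int | None    # None when collapsed over changes
    task: str | None             # None when collapsed over tasks
    values: np.ndarray
    trial_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def roi_beta_series(estimates: TrialEstimates,
                    voxel_mask: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean of voxel t per trial, order preserved."""
    t = estimates.t_stats
    if voxel_mask is not None:
        mask = np.asarray(voxel_mask)
        if mask.dtype == bool:
            if not mask.any():
                raise ValueError("empty ROI mask")
            t = t[:, mask]
        else:
            if mask.size == 0:
                raise ValueError("empty ROI mask")
            t = t[:, mask]
    if t.shape[1] == 0:
        raise ValueError("empty ROI mask")
    return t.mean(axis=1)


def bin_series(series: np.ndarray, trials: list[Trial],
               roi_name: str = "") -> list[BetaSeries]:
    """Bin per-trial scalars by (total_changes, task), trial order kept."""
    if len(series) != len(trials):
        raise ValueError("series length does not match trial list")
    bins: dict[tuple[int, str], tuple[list[float], list[int]]] = {}
    for value, trial in zip(series, trials):
        if trial.task is None or trial.total_changes is None:
            raise ValueError(f"trial {trial.trial_index} lacks condition labels")
        key = (trial.total_changes, trial.task)
        vals, idxs = bins.setdefault(key, ([], []))
        vals.append(float(value))
        idxs.append(trial.trial_index)
    return [
        BetaSeries(roi_name=roi_name, total_changes=c, task=task,
                   values=np.array(vals), trial_indices=np.array(idxs))
        for (c, task), (vals, idxs) in sorted(bins.items())
    ]


def beta_series_correlation(a: BetaSeries, b: BetaSeries) -> tuple[float, float]:
    """Pearson r between two matched beta-series and its Fisher z.

    Raises on constant input or |r| = 1 (infinite z) rather than clamping.
    """
    if len(a) != len(b):
        raise ValueError("beta-series lengths differ")
    if len(a) < 3:
        raise ValueError("need at least 3 trials per series")
    if not np.array_equal(a.trial_indices, b.trial_indices):
        raise ValueError("beta-series trial indices do not match")
    for s in (a, b):
        if np.ptp(s.values) == 0:
            raise ConstantSeriesError(
                f"constant beta-series for {s.roi_name} "
                f"({s.total_changes} changes, task {s.task})")
    r = float(np.corrcoef(a.values, b.values)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        raise PerfectCorrelationError(
            f"|r| = 1 between {a.roi_name} and {b.roi_name}: Fisher z infinite")
    return r, float(np.arctanh(r))


def pair_connectivity(estimates_by_roi: dict[str, list[TrialEstimates]],
                      schedule: TrialSchedule,
                      pairs: list[tuple[str, str]],
                      participant: str | int = 0,
                      voxel_masks: dict[str, np.ndarray] | None = None,
                      hemisphere: str = "left") -> pd.DataFrame:
    """Full beta-series connectivity table for one participant.

    ``estimates_by_roi`` maps ROI name to its per-scan image
    :class:`~hippopred.glm.TrialEstimates`.  Returns a tidy frame with
    columns :data:`TABLE_COLUMNS`.
    """
    trial_by_index = {t.trial_index: t for t in schedule.trials}
    binned: dict[str, list[BetaSeries]] = {}
    for roi, est_list in estimates_by_roi.items():
        mask = (voxel_masks or {}).get(roi)
        values, trials = [], []
        for est in sorted(est_list, key=lambda e: e.scan_index):
            values.append(roi_beta_series(est, mask))
            trials.extend(trial_by_index[i] for i in est.trial_indices)
        binned[roi] = bin_series(np.concatenate(values), trials, roi)
    rows = []
    for roi_a, roi_b in pairs:
        by_key_b = {(s.total_changes, s.task): s for s in binned[roi_b]}
        for sa in binned[roi_a]:
            sb = by_key_b[(sa.total_changes, sa.task)]
            r, z = beta_series_correlation(sa, sb)
            rows.append(dict(participant=participant, hemisphere=hemisphere,
                             pair=f"{roi_a}-{roi_b}", task=sa.task,
                             total_changes=sa.total_changes,
                             n_trials=len(sa), r=r, z=z))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def collapse_tasks(table: pd.DataFrame) -> pd.DataFrame:
    """Average the two tasks' Fisher-z values per participant/pair/changes.

    Raises if any (participant, pair, changes) cell lacks either task.
    """
    required = {"participant", "pair", "task", "total_changes", "z"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    tasks = sorted(table["task"].unique())
    if len(tasks) != 2:
        raise ValueError(f"expected 2 tasks, found {tasks}")
    keys = ["participant", "pair", "total_changes"]
    if "hemisphere" in table.columns:
        keys.insert(1, "hemisphere")
    counts = table.groupby(keys)["task"].nunique()
    bad = counts[counts < 2]
    if len(bad):
        missing = ", ".join(str(k) for k in bad.index.tolist())
        raise ValueError(f"missing task cell(s) for: {missing}")
    out = (table.groupby(keys, as_index=False)
           .agg(n_trials=("n_trials", "sum"), z=("z", "mean")))
    out["task"] = "collapsed"
    out["r"] = np.tanh(out["z"])
    if "hemisphere" not in out.columns:
        out["hemisphere"] = "left"
    return out[TABLE_COLUMNS]
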