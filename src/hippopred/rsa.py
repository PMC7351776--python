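"""Multivoxel pattern-similarity statistics in CA1.

Two statistics are computed from single-trial t-patterns:

* **prediction strength** — for each eligible cue, the correlation of the
  cue pattern with the intact (0-changes) image of the same room, minus
  the mean correlation with other rooms' intact images; positive values
  indicate room-specific reinstatement at cue.
* **prediction-error similarity** — within-trial correlation of the cue
  pattern with the same trial's probe-image pattern, aggregated per
  number of changes (0-4); a decrease with changes reflects growing
  divergence between the retrieved memory and the sensory evidence.

Eligibility rules for prediction strength: cues of 0-changes trials are
excluded (the matched image would share the trial); cue and intact image
must not share a scan (within-scan similarity is inflated) and must share
a task.  Per-pattern correlations are Fisher-transformed before any
subtraction or averaging, then averaged per task and across tasks.
Voxel selection drops the third of voxels least activated by the task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import PerfectCorrelationError
from .design import Trial, TrialSchedule
from .glm import ConditionActivation

logger = logging.getLogger(__name__)


class ConstantPatternError(ValueError):
    pass


def pattern_fisher_z(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher z of the Pearson correlation between two voxel patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("patterns must be 1-D and of equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantPatternError("constant voxel pattern: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise PerfectCorrelationError(
            f"|r| = {abs(r):.0f} between patterns: Fisher z infinite")
    return float(np.arctanh(r))


def _normalize_rows(patterns: np.ndarray, rows: np.ndarray,
                    keep: np.ndarray) -> np.ndarray:
    """Center and unit-norm selected rows/voxels; validates per row.

    Rows of the result dotted together give Pearson correlations.
    """
    sub = patterns[np.ix_(rows, keep)].astype(float)
    if np.isnan(sub).any():
        raise ValueError("pattern rows contain NaN for required trials")
    sub = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(sub, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ConstantPatternError("constant voxel pattern: correlation undefined")
    return sub / norms


def _fisher_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """atanh of all pairwise correlations of normalized pattern rows."""
    R = A @ B.T
    if (np.abs(R) >= 1.0 - 1e-12).any():
        raise PerfectCorrelationError("|r| = 1 between patterns: Fisher z infinite")
    return np.arctanh(R)


# ---------------------------------------------------------------------------
# voxel selection


@dataclass
class VoxelSelection:
    """Top-activated voxel subset used for all pattern statistics."""

    roi_name: str
    kept: np.ndarray              # indices, ascending
    dropped_fraction: float
    ranking_stat: np.ndarray      # per-voxel activation used for ranking

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def participant_task_mean_activation(
        activations: list[ConditionActivation]) -> np.ndarray:
    """Per-voxel mean activation across changes levels, runs and tasks.

    Runs are averaged within task first, then tasks averaged, mirroring
    the per-task structure of the condition GLM.
    """
    if not activations:
        raise ValueError("no condition activations given")
    by_task: dict[str, list[np.ndarray]] = {}
    for act in activations:
        by_task.setdefault(act.task, []).append(act.voxel_task_mean())
    task_means = [np.mean(v, axis=0) for v in by_task.values()]
    return np.mean(task_means, axis=0)


def select_active_voxels(activation: np.ndarray, fraction: float = 1.0 / 3.0,
                         roi_name: str = "CA1") -> VoxelSelection:
    """Keep the ``ceil((1 - fraction) * n)`` most activated voxels.

    Ties are broken by voxel index (lower index ranks higher), which makes
    the selection deterministic.
    """
    activation = np.asarray(activation, dtype=float)
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = activation.size
    if n < 2:
        raise ValueError("need at least 2 voxels to select from")
    n_keep = int(np.ceil((1.0 - fraction) * n - 1e-9))
    order = np.argsort(-activation, kind="stable")
    kept = np.sort(order[:n_keep])
    if np.ptp(activation) == 0 and n_keep < n:
        logger.info("all voxels tied; selection resolved by index order")
    return VoxelSelection(roi_name=roi_name, kept=kept,
                          dropped_fraction=fraction, ranking_stat=activation)


# ---------------------------------------------------------------------------
# cue/intact-image pair eligibility


@dataclass(frozen=True)
class PairRecord:
    cue_trial_index: int
    image_trial_index: int
    is_zero_change_cue: bool
    same_scan: bool
    cross_task: bool

    @property
    def eligible(self) -> bool:
        return not (self.is_zero_change_cue or self.same_scan or self.cross_task)


@dataclass
class PairEligibility:
    records: list[PairRecord]

    @property
    def eligible(self) -> list[PairRecord]:
        return [r for r in self.records if r.eligible]


def eligible_cue_pairs(schedule: TrialSchedule) -> PairEligibility:
    """Pair every cue trial with its room's 0-changes image trial.

    Flags each pair for the three exclusion rules; a pair is eligible iff
    all flags are false.  Raises if any room lacks a 0-changes trial.
    """
    zero_by_room: dict[str, Trial] = {}
    for t in schedule.trials:
        if t.total_changes == 0:
            zero_by_room[t.room_id] = t
    records = []
    for t in schedule.trials:
        if t.room_id not in zero_by_room:
            raise ValueError(f"room {t.room_id} has no 0-changes trial")
        zero = zero_by_room[t.room_id]
        records.append(PairRecord(
            cue_trial_index=t.trial_index,
            image_trial_index=zero.trial_index,
            is_zero_change_cue=t.total_changes == 0,
            same_scan=t.scan_index == zero.scan_index,
            cross_task=t.task != zero.task,
        ))
    return PairEligibility(records=records)


def _other_zero_trials(schedule: TrialSchedule, cue: Trial,
                       restrict: bool) -> list[Trial]:
    """Other rooms' 0-changes trials usable as the baseline for ``cue``."""
    out = []
    for t in schedule.trials:
        if t.total_changes != 0 or t.room_id == cue.room_id:
            continue
        if restrict and (t.scan_index == cue.scan_index or t.task != cue.task):
            continue
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# the two statistics


@dataclass
class PredictionStrengthResult:
    index_z: float                    # match-minus-other, Fisher-z units
    n_pairs: int
    per_task_z: dict[str, float]


def prediction_strength(cue_patterns: np.ndarray, image_patterns: np.ndarray,
                        selection: VoxelSelection, schedule: TrialSchedule,
                        restrict_others: bool = True
                        ) -> PredictionStrengthResult:
    """Room-specific reinstatement index for one participant.

    ``cue_patterns`` and ``image_patterns`` are (n_trials, n_voxels)
    arrays aligned to schedule trial indices (rows may be NaN for trials
    never used).  The "other rooms" baseline applies the same
    same-scan/same-task eligibility as the matched pair when
    ``restrict_others`` is set.
    """
    if selection.n_kept < 3:
        raise ValueError("need at least 3 kept voxels for pattern correlation")
    keep = selection.kept
    trial_by_index = {t.trial_index: t for t in schedule.trials}
    pairs = eligible_cue_pairs(schedule).eligible
    if not pairs:
        raise ValueError("no eligible cue/intact-image pairs in schedule")
    zero_trials = [t for t in schedule.trials if t.total_changes == 0]
    zero_pos = {t.trial_index: i for i, t in enumerate(zero_trials)}
    C = _normalize_rows(cue_patterns,
                        np.array([r.cue_trial_index for r in pairs]), keep)
    I0 = _normalize_rows(image_patterns,
                         np.array([t.trial_index for t in zero_trials]), keep)
    Z = _fisher_matrix(C, I0)
    per_task: dict[str, list[float]] = {}
    n_used = 0
    for row, rec in enumerate(pairs):
        cue_trial = trial_by_index[rec.cue_trial_index]
        others = _other_zero_trials(schedule, cue_trial, restrict_others)
        if not others:
            logger.info("cue trial %d dropped: no eligible other-room images",
                        rec.cue_trial_index)
            continue
        z_match = Z[row, zero_pos[rec.image_trial_index]]
        z_others = Z[row, [zero_pos[o.trial_index] for o in others]]
        per_task.setdefault(cue_trial.task, []).append(
            float(z_match - z_others.mean()))
        n_used += 1
    if not per_task:
        raise ValueError("all eligible cues dropped: no baseline images")
    task_means = {task: float(np.mean(v)) for task, v in per_task.items()}
    return PredictionStrengthResult(
        index_z=float(np.mean(list(task_means.values()))),
        n_pairs=n_used, per_task_z=task_means)


def prediction_error_similarity(cue_patterns: np.ndarray,
                                image_patterns: np.ndarray,
                                selection: VoxelSelection,
                                schedule: TrialSchedule) -> dict[int, float]:
    """Within-trial cue<->probe similarity per total-changes level.

    Per-trial Fisher z values are averaged within (changes, task) cells
    and then across tasks, returning one value per changes level 0-4.
    """
    keep = selection.kept
    rows = np.array([t.trial_index for t in schedule.trials])
    C = _normalize_rows(cue_patterns, rows, keep)
    I = _normalize_rows(image_patterns, rows, keep)
    r = np.einsum("ij,ij->i", C, I)
    if (np.abs(r) >= 1.0 - 1e-12).any():
        raise PerfectCorrelationError(
            "|r| = 1 between patterns: Fisher z infinite")
    z = np.arctanh(r)
    cells: dict[tuple[int, str], list[float]] = {}
    for i, t in enumerate(schedule.trials):
        cells.setdefault((t.total_changes, t.task), []).append(float(z[i]))
    return _collapse_cells(cells)


def other_room_control(cue_patterns: np.ndarray, image_patterns: np.ndarray,
                       selection: VoxelSelection, schedule: TrialSchedule,
                       restrict: bool = True) -> dict[int, float]:
    """Prediction-error similarity corrected by other-room similarity.

    From each trial's cue<->probe z, subtracts the mean z of the cue to
    other rooms' images of the same trial type (subject to the same
    scan/task eligibility when ``restrict`` is set).  Trials whose trial
    type has no other eligible room are dropped and logged.
    """
    keep = selection.kept
    by_type: dict[tuple[int, int], list[Trial]] = {}
    for t in schedule.trials:
        by_type.setdefault(t.trial_type, []).append(t)
    cells: dict[tuple[int, str], list[float]] = {}
    for ttype, group in by_type.items():
        rows = np.array([t.trial_index for t in group])
        C = _normalize_rows(cue_patterns, rows, keep)
        I = _normalize_rows(image_patterns, rows, keep)
        Z = _fisher_matrix(C, I)
        for i, t in enumerate(group):
            other_idx = [j for j, o in enumerate(group)
                         if o.room_id != t.room_id
                         and not (restrict and (o.scan_index == t.scan_index
                                                or o.task != t.task))]
            if not other_idx:
                logger.info("trial %d dropped: lone room in trial type %s",
                            t.trial_index, ttype)
                continue
            cells.setdefault((t.total_changes, t.task), []).append(
                float(Z[i, i] - Z[i, other_idx].mean()))
    return _collapse_cells(cells)


def _collapse_cells(cells: dict[tuple[int, str], list[float]]
                    ) -> dict[int, float]:
    by_changes: dict[int, dict[str, float]] = {}
    for (c, task), vals in cells.items():
        by_changes.setdefault(c, {})[task] = float(np.mean(vals))
    return {c: float(np.mean(list(tasks.values())))
            for c, tasks in sorted(by_changes.items())}
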