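"""Trial-schedule generation for the cued-retrieval change-detection task.

The task shows, on every trial, a room name (cue), a blank, and a probe
image of that room containing 0-2 furniture changes crossed with 0-2
layout changes (nine trial types).  Each of the 30 learned rooms appears
once in every trial type, split evenly between two blocked tasks
(Furniture / Layout) that alternate across scans.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS: tuple[str, str] = ("Furniture", "Layout")
CHANGE_LEVELS: tuple[int, ...] = (0, 1, 2)

#: the nine (furniture_changes, layout_changes) trial types
TRIAL_TYPES: tuple[tuple[int, int], ...] = tuple(
    (f, l) for f in CHANGE_LEVELS for l in CHANGE_LEVELS
)


class BalancingError(ValueError):
    """Raised when the factorial design cannot be split evenly."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial design and its trial timing.

    Defaults reproduce the study layout: 30 rooms x 9 trial types = 270
    trials over 10 scans (5 per task), cue 1.5 s -> blank 1 s -> image 4 s,
    TR 2.5 s.  Inter-trial intervals are drawn uniformly from
    ``iti_values_s`` (jitter at TR multiples keeps the design estimable).
    """

    n_rooms: int = 30
    tasks: tuple[str, str] = TASKS
    n_scans: int = 10
    cue_duration_s: float = 1.5
    blank_duration_s: float = 1.0
    image_duration_s: float = 4.0
    tr_s: float = 2.5
    iti_values_s: tuple[float, ...] = (2.5, 5.0)
    pre_rest_s: float = 10.0
    post_rest_s: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rooms < 2 or self.n_rooms % 2:
            raise ValueError("n_rooms must be even and >= 2 (rooms are split "
                             "evenly between the two tasks within each trial type)")
        if self.n_scans < 2 or self.n_scans % 2:
            raise BalancingError("n_scans must be even: tasks alternate and "
                                 "must receive an equal number of scans")
        if len(self.tasks) != 2 or len(set(self.tasks)) != 2:
            raise ValueError("exactly two distinct task labels required")
        for name in ("cue_duration_s", "blank_duration_s", "image_duration_s",
                     "tr_s", "pre_rest_s", "post_rest_s"):
            if getattr(self, name) <= 0 and name not in ("pre_rest_s",):
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.iti_values_s):
            raise ValueError("ITI values must be > 0")
        n_trials = self.n_rooms * len(TRIAL_TYPES)
        if n_trials % self.n_scans:
            raise BalancingError(
                f"{self.n_rooms} rooms x {len(TRIAL_TYPES)} trial types = "
                f"{n_trials} trials cannot be split evenly over "
                f"{self.n_scans} scans")

    @property
    def n_trials(self) -> int:
        return self.n_rooms * len(TRIAL_TYPES)

    @property
    def trials_per_scan(self) -> int:
        return self.n_trials // self.n_scans

    @property
    def cue_to_image_s(self) -> float:
        return self.cue_duration_s + self.blank_duration_s

    def scan_task(self, scan_index: int) -> str:
        """Task of a given scan; blocks alternate starting with tasks[0]."""
        return self.tasks[scan_index % 2]


@dataclass(frozen=True)
class Trial:
    """One cue->image trial."""

    trial_index: int
    room_id: str
    task: str
    furniture_changes: int
    layout_changes: int
    scan_index: int
    cue_onset_s: float
    image_onset_s: float

    @property
    def total_changes(self) -> int:
        return self.furniture_changes + self.layout_changes

    @property
    def trial_type(self) -> tuple[int, int]:
        return (self.furniture_changes, self.layout_changes)

    @property
    def trial_type_label(self) -> str:
        return f"f{self.furniture_changes}l{self.layout_changes}"


@dataclass(frozen=True)
class TrialSchedule:
    """A complete, ordered trial list together with its generating spec."""

    spec: DesignSpec
    trials: tuple[Trial, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def scan_trials(self, scan_index: int) -> list[Trial]:
        return [t for t in self.trials if t.scan_index == scan_index]

    def scan_duration_s(self, scan_index: int) -> float:
        """Scan length: last image offset plus the post-trial rest period."""
        trials = self.scan_trials(scan_index)
        if not trials:
            return self.spec.pre_rest_s + self.spec.post_rest_s
        end = max(t.image_onset_s for t in trials) + self.spec.image_duration_s
        return end + self.spec.post_rest_s

    def scan_timepoints(self, scan_index: int) -> int:
        return int(np.ceil(self.scan_duration_s(scan_index) / self.spec.tr_s))

    def counts_by_total_changes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.trials:
            out[t.total_changes] = out.get(t.total_changes, 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, in presentation order."""
        return pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in self.trials],
                "room_id": [t.room_id for t in self.trials],
                "task": [t.task for t in self.trials],
                "furniture_changes": [t.furniture_changes for t in self.trials],
                "layout_changes": [t.layout_changes for t in self.trials],
                "total_changes": [t.total_changes for t in self.trials],
                "scan_index": [t.scan_index for t in self.trials],
                "cue_onset_s": [t.cue_onset_s for t in self.trials],
                "image_onset_s": [t.image_onset_s for t in self.trials],
            }
        )


def room_label(i: int) -> str:
    return f"room{i:02d}"


def generate_schedule(spec: DesignSpec) -> TrialSchedule:
    """Generate a randomized schedule satisfying all design invariants.

    Each room appears exactly once per trial type; within each trial type
    half the rooms go to each task; each task's trials are distributed
    over its scans in equal numbers; tasks alternate across scans; onsets
    are strictly increasing within scan with jittered ITIs.
    """
    rng = np.random.default_rng(spec.seed)
    rooms = [room_label(i) for i in range(spec.n_rooms)]

    # (room, trial_type) -> task: split each trial type's rooms 50/50
    assignment: dict[str, list[tuple[str, int, int]]] = {t: [] for t in spec.tasks}
    half = spec.n_rooms // 2
    for (f, l) in TRIAL_TYPES:
        perm = rng.permutation(spec.n_rooms)
        for k, ridx in enumerate(perm):
            task = spec.tasks[0] if k < half else spec.tasks[1]
            assignment[task].append((rooms[ridx], f, l))

    per_scan = spec.trials_per_scan
    scans_per_task = spec.n_scans // 2
    # distribute each task's trials randomly over its scans
    scan_contents: dict[int, list[tuple[str, int, int]]] = {}
    for ti, task in enumerate(spec.tasks):
        pool = assignment[task]
        order = rng.permutation(len(pool))
        task_scans = [ti + 2 * s for s in range(scans_per_task)]
        for k, scan in enumerate(task_scans):
            idx = order[k * per_scan:(k + 1) * per_scan]
            scan_contents[scan] = [pool[j] for j in idx]

    trials: list[Trial] = []
    index = 0
    for scan in range(spec.n_scans):
        t = spec.pre_rest_s
        for room, f, l in scan_contents[scan]:
            iti = float(rng.choice(spec.iti_values_s))
            trials.append(Trial(
                trial_index=index,
                room_id=room,
                task=spec.scan_task(scan),
                furniture_changes=f,
                layout_changes=l,
                scan_index=scan,
                cue_onset_s=t,
                image_onset_s=t + spec.cue_to_image_s,
            ))
            index += 1
            t += spec.cue_to_image_s + spec.image_duration_s + iti
    return TrialSchedule(spec=spec, trials=tuple(trials))


# ---------------------------------------------------------------------------
# events TSV (BIDS dialect) serialization

EVENTS_COLUMNS = [
    "onset", "duration", "trial_type", "room_id", "task",
    "furniture_changes", "layout_changes", "scan_index", "event_kind",
]


class EventsParseError(ValueError):
    pass


def write_events(schedule: TrialSchedule, path) -> None:
    """Write the schedule as a tab-separated events table.

    Two rows per trial (cue and image), onsets in seconds from scan start,
    '.' as the missing-value marker, columns :data:`EVENTS_COLUMNS`.
    """
    rows = []
    spec = schedule.spec
    for t in schedule.trials:
        base = dict(trial_type=t.trial_type_label, room_id=t.room_id,
                    task=t.task, furniture_changes=t.furniture_changes,
                    layout_changes=t.layout_changes, scan_index=t.scan_index)
        rows.append(dict(onset=t.cue_onset_s, duration=spec.cue_duration_s,
                         event_kind="cue", **base))
        rows.append(dict(onset=t.image_onset_s, duration=spec.image_duration_s,
                         event_kind="image", **base))
    df = pd.DataFrame(rows, columns=EVENTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_events(path, spec: DesignSpec | None = None) -> TrialSchedule:
    """Read an events table back into a :class:`TrialSchedule`.

    The cue row of each trial carries the authoritative onset; the image
    row is matched by (room_id, trial_type).  Raises
    :class:`EventsParseError` naming the offending row on malformed input.
    """
    if spec is None:
        spec = DesignSpec()
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype=str)
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise EventsParseError(f"missing column(s): {', '.join(missing)}")
    for i, v in enumerate(df["onset"]):
        try:
            float(v)
        except (TypeError, ValueError):
            raise EventsParseError(f"non-numeric onset {v!r} in row {i}") from None

    cues = df[df["event_kind"] == "cue"].reset_index()
    images = df[df["event_kind"] == "image"].reset_index()
    for sub, kind in ((cues, "cue"), (images, "image")):
        dup = sub.duplicated(subset=["room_id", "trial_type"])
        if dup.any():
            row = sub.loc[dup.idxmax()]
            raise EventsParseError(
                f"duplicate (room, trial_type) {kind} row: "
                f"{row['room_id']}/{row['trial_type']} (row {row['index']})")
    img_lookup = {
        (r["room_id"], r["trial_type"]): r for _, r in images.iterrows()
    }
    trials: list[Trial] = []
    for _, r in cues.iterrows():
        key = (r["room_id"], r["trial_type"])
        if key not in img_lookup:
            raise EventsParseError(f"cue without matching image row: {key}")
        img = img_lookup[key]
        trials.append(Trial(
            trial_index=0,  # reassigned below in presentation order
            room_id=r["room_id"],
            task=r["task"],
            furniture_changes=int(r["furniture_changes"]),
            layout_changes=int(r["layout_changes"]),
            scan_index=int(r["scan_index"]),
            cue_onset_s=float(r["onset"]),
            image_onset_s=float(img["onset"]),
        ))
    trials.sort(key=lambda t: (t.scan_index, t.cue_onset_s))
    trials = [dataclasses.replace(t, trial_index=i) for i, t in enumerate(trials)]
    return TrialSchedule(spec=spec, trials=tuple(trials))
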