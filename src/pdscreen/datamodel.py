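"""Domain types and on-disk formats for mobile motor-assessment sessions.

A *session* is one recording of one task for one subject.  Tasks 1-11 cover
finger tapping (1, 2, 5), tremor (3, 4), tracing/drawing (6, 7, 8),
bimanual coordination (9), foot tapping (10) and gait (11).  Tapping and
tracing tasks produce touchscreen streams (time-stamped x/y samples);
tremor, foot-tapping and gait tasks produce accelerometer streams (3-axis
linear acceleration plus Euler angles).

Sessions for one subject are stored together in a single JSON file; the
extracted per-subject feature matrix is stored as a plain CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Task ids administered once per hand; all others are recorded once.
HAND_TASKS = frozenset({1, 2, 5, 6, 7, 8})
ALL_TASKS = tuple(range(1, 12))
#: Tasks whose raw data is an accelerometer stream rather than touches.
ACCEL_TASKS = frozenset({3, 4, 10, 11})

GROUPS = ("PD", "HC")
POINTERS = ("left", "right", "only")
EVENTS = ("down", "move", "up")


class ValidationError(ValueError):
    """A record or stream violates a structural invariant."""


def trail_centroid(trail: np.ndarray) -> tuple[float, float]:
    """Centroid of a polyline's vertices, dropping the duplicated endpoint
    of closed trails so it is not double-counted."""
    pts = np.asarray(trail, dtype=float)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


@dataclass(frozen=True)
class Circle:
    """Target circle in screen points (origin top-left, y downward)."""

    cx: float
    cy: float
    r: float

    def contains(self, x: float, y: float) -> bool:
        # boundary counts as inside
        return math.hypot(x - self.cx, y - self.cy) <= self.r


@dataclass
class TaskSpec:
    """Geometry and nominal timing of one task.

    ``circles`` are tapping targets; ``trails`` are ordered reference
    polylines ((n, 2) arrays) for tracing/coordination tasks.  Task 2 has
    exactly two circles (left, right); task 9 has two mirror-symmetric
    trails.
    """

    task_id: int
    circles: list[Circle] = field(default_factory=list)
    trails: list[np.ndarray] = field(default_factory=list)
    duration: float = 10.0

    def validate(self) -> None:
        if self.task_id not in ALL_TASKS:
            raise ValidationError(f"task_id {self.task_id} outside 1..11")
        if self.task_id == 2 and len(self.circles) != 2:
            raise ValidationError("task 2 requires exactly two target circles")
        if self.task_id == 9 and len(self.trails) != 2:
            raise ValidationError("task 9 requires two reference trails")


@dataclass
class TouchStream:
    """Time-stamped touchscreen samples for one session.

    ``t`` is seconds from session start and must be non-decreasing.
    ``pointer`` distinguishes the two hands in the coordination task
    ('left'/'right'); single-hand tasks use 'only'.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pointer: np.ndarray
    event: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, task_id: int | None = None) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.pointer) == len(self.event) == n):
            raise ValidationError("touch stream arrays have unequal lengths")
        if n and np.any(np.diff(self.t) < 0):
            where = f" in task {task_id}" if task_id else ""
            raise ValidationError(f"touch timestamps not monotone{where}")
        bad = set(np.unique(self.event)) - set(EVENTS)
        if bad:
            raise ValidationError(f"unknown touch events {sorted(bad)}")
        bad = set(np.unique(self.pointer)) - set(POINTERS)
        if bad:
            raise ValidationError(f"unknown pointers {sorted(bad)}")

    def for_pointer(self, pointer: str) -> "TouchStream":
        m = self.pointer == pointer
        return TouchStream(self.t[m], self.x[m], self.y[m], self.pointer[m], self.event[m])

    def moves(self) -> "TouchStream":
        m = (self.event == "move") | (self.event == "down")
        return TouchStream(self.t[m], self.x[m], self.y[m], self.pointer[m], self.event[m])


@dataclass
class AccelStream:
    """Uniformly sampled accelerometer + attitude stream.

    Acceleration is linear (gravity-removed) in m/s^2; roll/pitch/yaw are
    radians.  Timestamps must be strictly increasing; sampling deviating
    from uniform by more than 1% of the step is resampled on read.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    sample_rate: float

    def __len__(self) -> int:
        return len(self.t)

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def axes(self) -> dict[str, np.ndarray]:
        return {"x": self.ax, "y": self.ay, "z": self.az}

    def angles(self) -> dict[str, np.ndarray]:
        return {"roll": self.roll, "pitch": self.pitch, "yaw": self.yaw}

    def validate(self, task_id: int | None = None) -> None:
        n = len(self.t)
        arrays = (self.ax, self.ay, self.az, self.roll, self.pitch, self.yaw)
        if any(len(a) != n for a in arrays):
            raise ValidationError("accel stream arrays have unequal lengths")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                where = f" in task {task_id}" if task_id else ""
                raise ValidationError(f"accel timestamps not strictly increasing{where}")

    def is_uniform(self, tol: float = 0.01) -> bool:
        if len(self.t) < 3:
            return True
        dt = np.diff(self.t)
        step = 1.0 / self.sample_rate
        return bool(np.all(np.abs(dt - step) <= tol * step))

    def resampled(self, tol: float = 0.01) -> "AccelStream":
        """Return self if uniform within ``tol``, else a linearly
        interpolated stream on a uniform grid at ``sample_rate``."""
        if self.is_uniform(tol):
            return self
        tt = np.arange(self.t[0], self.t[-1] + 1e-12, 1.0 / self.sample_rate)
        interp = lambda a: np.interp(tt, self.t, a)  # noqa: E731
        return AccelStream(
            tt, interp(self.ax), interp(self.ay), interp(self.az),
            interp(self.roll), interp(self.pitch), interp(self.yaw), self.sample_rate,
        )


@dataclass
class TaskSession:
    task_id: int
    hand: str | None  # 'L' / 'R' for per-hand tasks, else None
    spec: TaskSpec | None = None
    touch: TouchStream | None = None
    accel: AccelStream | None = None

    @property
    def key(self) -> str:
        return session_key(self.task_id, self.hand)

    def validate(self) -> None:
        if self.task_id not in ALL_TASKS:
            raise ValidationError(f"task_id {self.task_id} outside 1..11")
        if self.hand not in (None, "L", "R"):
            raise ValidationError(f"hand must be L/R/None, got {self.hand!r}")
        if self.hand is not None and self.task_id not in HAND_TASKS:
            raise ValidationError(f"task {self.task_id} is not a per-hand task")
        if self.spec is not None:
            self.spec.validate()
        if self.touch is not None:
            self.touch.validate(self.task_id)
        if self.accel is not None:
            self.accel.validate(self.task_id)


def session_key(task_id: int, hand: str | None) -> str:
    return f"{task_id}{hand}" if hand else str(task_id)


@dataclass
class SubjectRecord:
    """Metadata, clinical labels and all task sessions for one participant.

    ``updrs3_score`` is the MDS-UPDRS Part III motor total (0-132 in the
    clinical instrument; 0-68 in this cohort); ``hy_stage`` is the Hoehn &
    Yahr stage with 0 reserved for healthy controls.
    """

    subject_id: str
    group: str
    updrs3_score: int
    hy_stage: int
    moca: int
    age: float
    gender: str
    sessions: dict[str, TaskSession] = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be PD or HC, got {self.group!r}")
        if self.group == "HC" and self.hy_stage != 0:
            raise ValidationError(
                f"subject {self.subject_id}: HC must have hy_stage 0, got {self.hy_stage}"
            )
        if self.group == "PD" and not (1 <= self.hy_stage <= 5):
            raise ValidationError(
                f"subject {self.subject_id}: PD hy_stage must be 1..5, got {self.hy_stage}"
            )
        if self.updrs3_score < 0:
            raise ValidationError("updrs3_score must be >= 0")
        if not (0 <= self.moca <= 30):
            raise ValidationError("moca must be in 0..30")
        for key, ses in self.sessions.items():
            if key != ses.key:
                raise ValidationError(f"session key {key!r} does not match {ses.key!r}")
            ses.validate()

    def session(self, task_id: int, hand: str | None = None) -> TaskSession | None:
        return self.sessions.get(session_key(task_id, hand))

    def add_session(self, ses: TaskSession) -> None:
        self.sessions[ses.key] = ses


# ---------------------------------------------------------------------------
# session JSON

def _spec_to_json(spec: TaskSpec | None):
    if spec is None:
        return None
    return {
        "circles": [{"cx": c.cx, "cy": c.cy, "r": c.r} for c in spec.circles],
        "trails": [np.asarray(t).tolist() for t in spec.trails],
        "duration": spec.duration,
    }


def _spec_from_json(task_id: int, obj) -> TaskSpec | None:
    if obj is None:
        return None
    trails = obj.get("trails")
    if trails is None and obj.get("trail") is not None:
        trails = [obj["trail"]]
    return TaskSpec(
        task_id=task_id,
        circles=[Circle(c["cx"], c["cy"], c["r"]) for c in obj.get("circles", [])],
        trails=[np.asarray(t, dtype=float) for t in (trails or [])],
        duration=float(obj.get("duration", 10.0)),
    )


def record_to_json(record: SubjectRecord) -> dict:
    sessions = []
    for key in sorted(record.sessions):
        ses = record.sessions[key]
        entry: dict = {"task_id": ses.task_id, "hand": ses.hand,
                       "task_spec": _spec_to_json(ses.spec)}
        if ses.touch is not None:
            s = ses.touch
            entry["touch"] = [
                [float(s.t[i]), float(s.x[i]), float(s.y[i]), str(s.pointer[i]), str(s.event[i])]
                for i in range(len(s))
            ]
        if ses.accel is not None:
            a = ses.accel
            entry["accel"] = {
                "rate": a.sample_rate,
                "samples": np.column_stack(
                    [a.t, a.ax, a.ay, a.az, a.roll, a.pitch, a.yaw]
                ).tolist(),
            }
        sessions.append(entry)
    return {
        "subject_id": record.subject_id,
        "group": record.group,
        "updrs3_score": int(record.updrs3_score),
        "hy_stage": int(record.hy_stage),
        "moca": int(record.moca),
        "age": float(record.age),
        "gender": record.gender,
        "sessions": sessions,
    }


def record_from_json(obj: Mapping) -> SubjectRecord:
    record = SubjectRecord(
        subject_id=str(obj["subject_id"]),
        group=str(obj["group"]),
        updrs3_score=int(obj["updrs3_score"]),
        hy_stage=int(obj["hy_stage"]),
        moca=int(obj["moca"]),
        age=float(obj["age"]),
        gender=str(obj["gender"]),
    )
    for entry in obj.get("sessions", []):
        task_id = int(entry["task_id"])
        touch = None
        if entry.get("touch") is not None:
            rows = entry["touch"]
            touch = TouchStream(
                t=np.array([r[0] for r in rows], dtype=float),
                x=np.array([r[1] for r in rows], dtype=float),
                y=np.array([r[2] for r in rows], dtype=float),
                pointer=np.array([r[3] for r in rows], dtype="U5"),
                event=np.array([r[4] for r in rows], dtype="U4"),
            )
        accel = None
        if entry.get("accel") is not None:
            arr = np.asarray(entry["accel"]["samples"], dtype=float).reshape(-1, 7)
            accel = AccelStream(
                arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                arr[:, 4], arr[:, 5], arr[:, 6],
                sample_rate=float(entry["accel"]["rate"]),
            )
        record.add_session(TaskSession(
            task_id=task_id,
            hand=entry.get("hand"),
            spec=_spec_from_json(task_id, entry.get("task_spec")),
            touch=touch,
            accel=accel,
        ))
    record.validate()
    return record


def write_session_file(record: SubjectRecord, path: str | Path) -> None:
    record.validate()
    Path(path).write_text(json.dumps(record_to_json(record)))


def read_session_file(path: str | Path) -> SubjectRecord:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed session JSON in {path}: {exc}") from exc
    return record_from_json(obj)


# ---------------------------------------------------------------------------
# feature table

LABEL_COLUMNS = ("group", "updrs3_score", "hy_stage")


@dataclass
class FeatureTable:
    """Subjects x named-features matrix plus per-subject label columns.

    Feature names follow ``task{k}[_{L|R}]_{feature}`` so every feature
    maps to exactly one task.  ``features`` and ``labels`` share the same
    subject index.
    """

    features: pd.DataFrame
    labels: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def validate(self) -> None:
        if self.features.columns.duplicated().any():
            dupes = self.features.columns[self.features.columns.duplicated()]
            raise ValidationError(f"duplicate feature names: {sorted(set(dupes))}")
        if not self.features.index.equals(self.labels.index):
            raise ValidationError("feature and label indices differ")
        for col in LABEL_COLUMNS:
            if col not in self.labels.columns:
                raise ValidationError(f"missing label column {col!r}")
        for name in self.features.columns:
            feature_task(name)  # raises if unparsable

    def task_subset(self, task_id: int) -> "FeatureTable":
        cols = [c for c in self.features.columns if feature_task(c) == task_id]
        return FeatureTable(self.features[cols].copy(), self.labels.copy())


def feature_task(name: str) -> int:
    """Task id a feature column belongs to (parsed from its ``task{k}_`` prefix)."""
    if not name.startswith("task"):
        raise ValidationError(f"feature {name!r} has no task prefix")
    head = name[4:].split("_", 1)[0]
    try:
        task_id = int(head)
    except ValueError as exc:
        raise ValidationError(f"feature {name!r} has no task prefix") from exc
    if task_id not in ALL_TASKS:
        raise ValidationError(f"feature {name!r} maps to invalid task {task_id}")
    return task_id


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.validate()
    df = pd.concat([table.labels[list(LABEL_COLUMNS)], table.features], axis=1)
    df.index.name = "subject_id"
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    df.index.name = None
    labels = df[list(LABEL_COLUMNS)].copy()
    features = df.drop(columns=list(LABEL_COLUMNS))
    table = FeatureTable(features, labels)
    table.validate()
    return table


def build_feature_table(
    vectors: Mapping[str, Mapping[str, float]],
    records: Iterable[SubjectRecord],
    impute: bool = True,
) -> FeatureTable:
    """Assemble per-subject feature vectors into a FeatureTable.

    Missing values (absent sessions or undefined features) are imputed
    with the column median and the affected cells recorded in
    ``table.labels['n_imputed']``.  A column that is missing for every
    subject is filled with 0.
    """
    recs = {r.subject_id: r for r in records}
    features = pd.DataFrame.from_dict({sid: dict(v) for sid, v in vectors.items()},
                                      orient="index")
    features = features.loc[list(vectors.keys())]
    labels = pd.DataFrame(
        {
            "group": [recs[s].group for s in features.index],
            "updrs3_score": [recs[s].updrs3_score for s in features.index],
            "hy_stage": [recs[s].hy_stage for s in features.index],
        },
        index=features.index,
    )
    if impute:
        n_missing = features.isna().sum(axis=1)
        med = features.median()
        features = features.fillna(med).fillna(0.0)
        labels["n_imputed"] = n_missing
    table = FeatureTable(features, labels)
    table.validate()
    return table
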