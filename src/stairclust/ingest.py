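"""Reading accelerometer recordings and activity annotations.

Recordings are CSV files with columns ``time,x,y,z`` (time in seconds,
acceleration in g).  Annotations are interval CSVs with columns
``start,end,label`` where the label is one of the five walking activities
(``flat``, ``uphill``, ``downhill``, ``upstairs``, ``downstairs``); any
other string is mapped to ``other`` and excluded downstream.

Label resolution level 0 consolidates flat, uphill and downhill into a
single ``Walk`` identity so that the analysis reduces to distinguishing
ground walking from stair ambulation; level 1 keeps all five activities.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: the five annotated walking activities
KNOWN_ACTIVITIES = ("flat", "uphill", "downhill", "upstairs", "downstairs")
STAIR_ACTIVITIES = ("upstairs", "downstairs")
OTHER_LABEL = "other"
WALK_LABEL = "Walk"


class FormatError(ValueError):
    """Raised when an input file violates the expected CSV contract."""


class ResolutionLevel(enum.Enum):
    """Granularity of ground-truth activity labels.

    ``LEVEL0`` maps flat/uphill/downhill to a single ``Walk`` label and
    keeps the two stair labels; ``LEVEL1`` keeps all five activities.
    """

    LEVEL0 = "level0"
    LEVEL1 = "level1"

    def map_label(self, label: str) -> str:
        label = label.lower() if label != WALK_LABEL else label
        if self is ResolutionLevel.LEVEL1:
            return label if label in KNOWN_ACTIVITIES else (
                label if label == WALK_LABEL else OTHER_LABEL
            )
        if label == WALK_LABEL or label in ("flat", "uphill", "downhill"):
            return WALK_LABEL
        if label in STAIR_ACTIVITIES:
            return label
        return OTHER_LABEL


@dataclass
class Recording:
    """A single-subject tri-axial accelerometer time series.

    ``t`` is in seconds and strictly increasing; ``accel`` is an
    ``(n, 3)`` array in g units.
    """

    subject_id: str
    t: np.ndarray
    accel: np.ndarray
    sampling_rate: float = 20.0
    placement: str = "thigh_right"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have exactly 3 channels")
        if len(self.t) != len(self.accel):
            raise ValueError("t and accel lengths differ")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise FormatError(f"time not strictly increasing at row {row}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds, counting the final sample period."""
        return len(self.t) / self.sampling_rate


@dataclass
class LabelTrack:
    """Ground-truth activity intervals ``(start, end, activity)`` in seconds."""

    intervals: list[tuple[float, float, str]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda x: (x[0], x[1]))
        for (s, e, _) in iv:
            if not s < e:
                raise ValueError(f"interval start {s} not before end {e}")
        for a, b in zip(iv, iv[1:]):
            if b[0] < a[1]:
                raise ValueError(
                    f"overlapping intervals ({a[0]}, {a[1]}, {a[2]!r}) and "
                    f"({b[0]}, {b[1]}, {b[2]!r})"
                )
        self.intervals = iv


def read_recording(
    path: str | Path,
    sampling_rate: float = 20.0,
    subject_id: str | None = None,
    placement: str = "thigh_right",
) -> Recording:
    """Read an accelerometer CSV with columns ``time,x,y,z``.

    Validates a strictly increasing time base and reports sampling gaps
    larger than two sample periods in ``Recording.warnings``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    for col in ("time", "x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = int((vals.isna()).idxmax())
            raise FormatError(f"{path.name}: non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise FormatError(f"{path.name}: time not strictly increasing at row {row}")
    warnings: list[str] = []
    gap_thresh = 2.0 / sampling_rate
    for i in np.nonzero(dt > gap_thresh)[0]:
        warnings.append(
            f"gap of {dt[i]:.3f} s between t={t[i]:.3f} and t={t[i + 1]:.3f}"
        )
    return Recording(
        subject_id=subject_id or path.stem,
        t=t,
        accel=df[["x", "y", "z"]].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        placement=placement,
        warnings=warnings,
    )


def read_labels(path: str | Path) -> LabelTrack:
    """Read an interval annotation CSV with columns ``start,end,label``.

    Labels are case-insensitive; unknown strings map to ``other`` with a
    warning.  Overlapping intervals raise an error naming the pair.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("start", "end", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    warnings: list[str] = []
    intervals: list[tuple[float, float, str]] = []
    for i, row in df.iterrows():
        label = str(row["label"]).strip().lower()
        if label not in KNOWN_ACTIVITIES:
            warnings.append(f"row {i}: unknown label {row['label']!r} mapped to 'other'")
            label = OTHER_LABEL
        intervals.append((float(row["start"]), float(row["end"]), label))
    return LabelTrack(intervals=intervals, warnings=warnings)


def _stair_first_order(label: str) -> tuple[int, str]:
    # ties broken toward the rarer (stair) class so purity stays conservative
    return (0 if label in STAIR_ACTIVITIES else 1, label)


def window_labels(
    track: LabelTrack,
    window_starts: Sequence[float],
    window_len: float,
    level: ResolutionLevel = ResolutionLevel.LEVEL0,
) -> list[str]:
    """Assign each analysis window the majority-duration activity label.

    Resolution mapping is applied before the majority vote.  Windows whose
    duration is more than half uncovered or labelled ``other`` receive
    ``other`` (excluded downstream).  Duration ties are broken toward the
    stair labels.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    out: list[str] = []
    for ws in window_starts:
        we = ws + window_len
        durations: dict[str, float] = {}
        covered = 0.0
        for (s, e, label) in track.intervals:
            lo, hi = max(s, ws), min(e, we)
            if hi <= lo:
                continue
            mapped = level.map_label(label)
            durations[mapped] = durations.get(mapped, 0.0) + (hi - lo)
            covered += hi - lo
        other_time = durations.get(OTHER_LABEL, 0.0) + (window_len - covered)
        if other_time > window_len / 2:
            out.append(OTHER_LABEL)
            continue
        durations.pop(OTHER_LABEL, None)
        if not durations:
            out.append(OTHER_LABEL)
            continue
        top = max(durations.values())
        tied = sorted((k for k, v in durations.items() if v == top), key=_stair_first_order)
        out.append(tied[0])
    return out
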