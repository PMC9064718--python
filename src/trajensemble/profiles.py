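"""Data model and I/O for irregular longitudinal biomarker profiles.

A profile (trajectory) is one subject's time-ordered sequence of
measurements for a single marker.  Visit times are recorded (typically in
months) but the elastic distances downstream operate on the ordered value
sequence only, so profiles of different lengths and with irregular visit
spacing are first-class citizens: no interpolation or imputation is ever
performed.

Values at assay quantitation limits are clamped and flagged rather than
dropped, mirroring how censored viral-load measurements are handled in
practice.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensorFlag",
    "Trajectory",
    "ProfileSet",
    "LabeledProfileSet",
    "read_long_csv",
    "write_long_csv",
    "filter_min_visits",
    "log10_values",
    "censor_limits",
]


class CensorFlag(enum.Enum):
    """Per-point censoring status with respect to assay quantitation limits."""

    NONE = "none"
    AT_LOWER_LIMIT = "at_lower_limit"
    AT_UPPER_LIMIT = "at_upper_limit"


@dataclass(frozen=True)
class Trajectory:
    """One subject's ordered (time, value) sequence for one marker.

    Parameters
    ----------
    subject_id:
        Subject identifier, unique within a :class:`ProfileSet`.
    marker:
        Biomarker name (e.g. ``"cd4"`` or ``"vl"``).
    times:
        Strictly increasing visit times (months; integers accepted as reals).
    values:
        Measurements aligned with ``times``.
    censor_flags:
        Per-point :class:`CensorFlag`; defaults to all-uncensored.
    """

    subject_id: str
    marker: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    censor_flags: tuple[CensorFlag, ...] = field(default=())

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        flags = tuple(self.censor_flags) or tuple(
            CensorFlag.NONE for _ in values
        )
        if len(times) < 1:
            raise ValueError(
                f"trajectory {self.subject_id!r} must contain at least one point"
            )
        if not (len(times) == len(values) == len(flags)):
            raise ValueError(
                f"trajectory {self.subject_id!r}: times/values/censor_flags "
                f"lengths differ ({len(times)}/{len(values)}/{len(flags)})"
            )
        for a, b in zip(times, times[1:]):
            if not a < b:
                raise ValueError(
                    f"trajectory {self.subject_id!r}: times must be strictly "
                    f"increasing (found {a} followed by {b})"
                )
        for t, v in zip(times, values):
            if not (math.isfinite(t) and math.isfinite(v)):
                raise ValueError(
                    f"trajectory {self.subject_id!r}: non-finite point "
                    f"(time={t}, value={v})"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "censor_flags", flags)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass(frozen=True)
class ProfileSet:
    """A collection of trajectories for one marker with a stable subject order.

    Subject order is explicit and preserved by every operation; all distance
    matrices and cluster label vectors downstream index subjects in this
    order.
    """

    trajectories: tuple[Trajectory, ...]
    marker: str = ""

    def __post_init__(self) -> None:
        trajs = tuple(self.trajectories)
        seen: set[str] = set()
        for t in trajs:
            if t.subject_id in seen:
                raise ValueError(f"duplicate subject_id {t.subject_id!r}")
            seen.add(t.subject_id)
        marker = self.marker
        markers = {t.marker for t in trajs}
        if len(markers) > 1:
            raise ValueError(
                f"all trajectories must share one marker, found {sorted(markers)}"
            )
        if not marker and markers:
            marker = next(iter(markers))
        object.__setattr__(self, "trajectories", trajs)
        object.__setattr__(self, "marker", marker)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(t.subject_id for t in self.trajectories)

    def value_sequences(self) -> list[np.ndarray]:
        """Ordered value vectors, one per subject (what the distances see)."""
        return [t.values_array for t in self.trajectories]


@dataclass(frozen=True)
class LabeledProfileSet:
    """Profiles plus one ground-truth class label per subject."""

    profile_set: ProfileSet
    labels: tuple = ()

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) != len(self.profile_set):
            raise ValueError(
                f"{len(labels)} labels for {len(self.profile_set)} subjects"
            )
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.profile_set)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return self.profile_set.subject_ids


_COLUMNS = ["subject_id", "time", "marker", "value"]


def read_long_csv(path, marker: str | None = None) -> ProfileSet:
    """Read a long-format measurement table into a :class:`ProfileSet`.

    The file must have columns ``subject_id,time,marker,value``; missing
    visits are simply absent rows (no NA sentinel).  Subject order is the
    order of first appearance in the file; each subject's points are sorted
    by time.

    Parameters
    ----------
    path:
        CSV file path.
    marker:
        If the file holds several markers, the one to extract.  A file with
        a single marker needs no filter.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "marker": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if marker is not None:
        df = df[df["marker"] == marker]
    markers = df["marker"].unique()
    if len(markers) > 1:
        raise ValueError(
            f"{path}: multiple markers {sorted(markers)} present; "
            "pass marker= to select one"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"{path}: non-numeric value {df.loc[bad[0], 'value']!r} "
            f"at row {int(bad[0]) + 2}"
        )
    df = df.assign(value=values)
    if df["value"].isna().any():
        row = int(df.index[df["value"].isna()][0]) + 2
        raise ValueError(f"{path}: empty value at row {row}")
    dup = df.duplicated(subset=["subject_id", "time"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (subject_id, time) pair "
            f"({first['subject_id']!r}, {first['time']!r})"
        )
    marker_name = str(markers[0]) if len(markers) else (marker or "")
    trajs = []
    for sid in df["subject_id"].drop_duplicates():
        sub = df[df["subject_id"] == sid].sort_values("time", kind="stable")
        trajs.append(
            Trajectory(
                subject_id=str(sid),
                marker=marker_name,
                times=tuple(float(t) for t in sub["time"]),
                values=tuple(float(v) for v in sub["value"]),
            )
        )
    return ProfileSet(trajectories=tuple(trajs), marker=marker_name)


def write_long_csv(profile_set: ProfileSet, path) -> None:
    """Write a :class:`ProfileSet` in the same long CSV dialect read_long_csv reads.

    Numbers are written with :func:`repr`-exact decimal text so a read/write
    round trip preserves every (subject, time, value) triple bit-for-bit.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_COLUMNS) + "\n")
        for traj in profile_set:
            for t, v in zip(traj.times, traj.values):
                fh.write(
                    f"{traj.subject_id},{_fmt(t)},{traj.marker},{_fmt(v)}\n"
                )


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(x)


def filter_min_visits(profile_set: ProfileSet, min_visits: int) -> ProfileSet:
    """Retain exactly the subjects with at least ``min_visits`` measurement points.

    Subject order is preserved.  Idempotent.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    kept = tuple(t for t in profile_set if len(t) >= min_visits)
    return ProfileSet(trajectories=kept, marker=profile_set.marker)


def log10_values(profile_set: ProfileSet) -> ProfileSet:
    """Replace every value by its base-10 logarithm (times and flags unchanged).

    Applied to viral load before distance computation; raises on any
    non-positive value, naming the offending subject and time.
    """
    out = []
    for traj in profile_set:
        for t, v in zip(traj.times, traj.values):
            if v <= 0:
                raise ValueError(
                    f"log10 undefined for value {v} "
                    f"(subject {traj.subject_id!r}, time {t})"
                )
        out.append(
            Trajectory(
                subject_id=traj.subject_id,
                marker=traj.marker,
                times=traj.times,
                values=tuple(math.log10(v) for v in traj.values),
                censor_flags=traj.censor_flags,
            )
        )
    return ProfileSet(trajectories=tuple(out), marker=profile_set.marker)


def censor_limits(
    profile_set: ProfileSet, lower: float, upper: float
) -> ProfileSet:
    """Clamp values to assay quantitation limits and flag the clamped points.

    Values below ``lower`` become ``lower`` flagged ``AT_LOWER_LIMIT``;
    values above ``upper`` become ``upper`` flagged ``AT_UPPER_LIMIT``;
    in-range values are untouched.  Nothing is dropped: censored values are
    clustered as observed.
    """
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    out = []
    for traj in profile_set:
        values: list[float] = []
        flags: list[CensorFlag] = []
        for v, f in zip(traj.values, traj.censor_flags):
            if v < lower:
                values.append(float(lower))
                flags.append(CensorFlag.AT_LOWER_LIMIT)
            elif v > upper:
                values.append(float(upper))
                flags.append(CensorFlag.AT_UPPER_LIMIT)
            else:
                values.append(v)
                flags.append(f)
        out.append(
            Trajectory(
                subject_id=traj.subject_id,
                marker=traj.marker,
                times=traj.times,
                values=tuple(values),
                censor_flags=tuple(flags),
            )
        )
    return ProfileSet(trajectories=tuple(out), marker=profile_set.marker)
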