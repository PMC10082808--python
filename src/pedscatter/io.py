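"""Reading and writing of trajectory and annotation tables.

Trajectories are plain CSV files with columns ``time,id,x,y`` (seconds,
opaque id token, meters).  A small dialect layer maps alternative column
names and units — notably millimeter coordinates, the convention of
range-sensor pedestrian datasets — onto the canonical SI layout.  Time is a
float number of seconds from an arbitrary epoch; only differences matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

RELATION_LABELS = frozenset({"colleagues", "couples", "family", "friends"})
INTENSITY_LABELS = frozenset({"0", "1", "2", "3"})


@dataclass
class Dialect:
    """Column-name and unit mapping for a trajectory file flavor."""

    column_map: dict
    length_scale: float = 1.0  # multiply coordinates by this to get meters
    time_scale: float = 1.0    # multiply time by this to get seconds


DIALECTS: dict[str, Dialect] = {
    # canonical: time[s], id, x[m], y[m]
    "si": Dialect(column_map={"time": "time", "id": "id", "x": "x", "y": "y"}),
    # range-sensor convention: time[ms], person id, x[mm], y[mm]
    "mm": Dialect(
        column_map={"time": "time", "id": "id", "x": "x", "y": "y"},
        length_scale=1e-3,
        time_scale=1e-3,
    ),
}


@dataclass
class TrajectoryTable:
    """Time-ordered pedestrian positions.

    ``data`` has columns ``time`` (s), ``id`` (str), ``x``, ``y`` (m), sorted
    by (id, time).  ``sampling_period`` is the nominal sampling period in
    seconds (median time step if inferred).
    """

    data: pd.DataFrame
    sampling_period: float | None = None

    def __post_init__(self) -> None:
        required = {"time", "id", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"trajectory table missing columns: {sorted(missing)}")
        df = self.data.copy()
        df["id"] = df["id"].astype(str)
        df = df.sort_values(["id", "time"], kind="mergesort").reset_index(drop=True)
        if not np.isfinite(df[["time", "x", "y"]].to_numpy()).all():
            raise ValidationError("trajectory table contains non-finite values")
        for pid, g in df.groupby("id", sort=False):
            dt = np.diff(g["time"].to_numpy())
            if (dt <= 0).any():
                raise ValidationError(
                    f"non-increasing timestamps for pedestrian {pid!r}"
                )
        self.data = df
        if self.sampling_period is None:
            steps = df.groupby("id")["time"].diff().dropna()
            if len(steps):
                self.sampling_period = float(steps.median())

    @property
    def pedestrian_ids(self) -> list[str]:
        return list(self.data["id"].unique())

    def pedestrian(self, pid: str) -> pd.DataFrame:
        if not hasattr(self, "_by_id"):
            self._by_id = {
                k: g.reset_index(drop=True)
                for k, g in self.data.groupby("id", sort=False)
            }
        return self._by_id[str(pid)]


@dataclass
class AnnotationTable:
    """Dyad membership and social-class labels.

    ``label_scheme`` is ``"relation"`` (colleagues/couples/family/friends),
    ``"intensity"`` (interaction levels 0-3) or ``"custom"`` with an explicit
    ``label_set``.
    """

    data: pd.DataFrame
    label_scheme: str = "relation"
    label_set: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        required = {"group_id", "member_id_1", "member_id_2", "class_label"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"annotation table missing columns: {sorted(missing)}")
        df = self.data.copy()
        for col in ("group_id", "member_id_1", "member_id_2", "class_label"):
            df[col] = df[col].astype(str)
        if self.label_scheme == "relation":
            allowed = RELATION_LABELS
        elif self.label_scheme == "intensity":
            allowed = INTENSITY_LABELS
        elif self.label_scheme == "custom":
            allowed = frozenset(self.label_set) or frozenset(df["class_label"])
        else:
            raise ValidationError(f"unknown label scheme {self.label_scheme!r}")
        self.label_set = frozenset(allowed)
        bad = set(df["class_label"]) - allowed
        if bad:
            raise ValidationError(
                f"labels {sorted(bad)} not in {self.label_scheme!r} scheme"
            )
        same = df["member_id_1"] == df["member_id_2"]
        if same.any():
            raise ValidationError(
                f"group(s) {df.loc[same, 'group_id'].tolist()} list one "
                "pedestrian twice"
            )
        members = pd.concat([df["member_id_1"], df["member_id_2"]])
        dup = members[members.duplicated()]
        if len(dup):
            raise ValidationError(
                f"pedestrian(s) {sorted(set(dup))} appear in more than one group"
            )
        self.data = df.reset_index(drop=True)

    def validate_against(self, trajectories: TrajectoryTable) -> None:
        """Check that every member id has a trajectory."""
        known = set(trajectories.pedestrian_ids)
        members = set(self.data["member_id_1"]) | set(self.data["member_id_2"])
        missing = members - known
        if missing:
            raise ValidationError(
                f"annotated pedestrian(s) {sorted(missing)} absent from trajectories"
            )

    @property
    def group_members(self) -> set[str]:
        return set(self.data["member_id_1"]) | set(self.data["member_id_2"])


def read_trajectories(
    path: str | Path,
    dialect: str | Dialect = "si",
    sampling_period: float | None = None,
) -> TrajectoryTable:
    """Read a trajectory CSV, applying the dialect's column/unit mapping."""
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise FormatError(f"unknown trajectory dialect {dialect!r}") from None
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read trajectory file {path}: {exc}") from exc
    inverse = {v: k for k, v in dialect.column_map.items()}
    missing = set(dialect.column_map.values()) - set(raw.columns)
    if missing:
        raise FormatError(f"trajectory file {path} missing columns {sorted(missing)}")
    df = raw.rename(columns=inverse)[["time", "id", "x", "y"]].copy()
    df["time"] = df["time"].astype(float) * dialect.time_scale
    df["x"] = df["x"].astype(float) * dialect.length_scale
    df["y"] = df["y"].astype(float) * dialect.length_scale
    return TrajectoryTable(df, sampling_period=sampling_period)


def write_trajectories(table: TrajectoryTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, columns=["time", "id", "x", "y"])


def read_annotations(
    path: str | Path,
    label_scheme: str = "relation",
    trajectories: TrajectoryTable | None = None,
    label_set: frozenset = frozenset(),
) -> AnnotationTable:
    """Read a dyad annotation CSV (group_id, member_id_1, member_id_2,
    class_label); optionally cross-check member ids against a trajectory
    table."""
    try:
        raw = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read annotation file {path}: {exc}") from exc
    table = AnnotationTable(raw, label_scheme=label_scheme, label_set=label_set)
    if trajectories is not None:
        table.validate_against(trajectories)
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.data.to_csv(
        path, index=False,
        columns=["group_id", "member_id_1", "member_id_2", "class_label"],
    )
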