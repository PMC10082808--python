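"""From raw trajectories to group-centered encounter series.

The reduction proceeds in four steps: (1) atypical motion (waiting, running)
is removed by keeping maximal segments of normal walking speed; (2) each
annotated dyad is collapsed to a single unit — the geometrical center of its
two members — with the member separation attached; (3) candidate
group-individual pairs are screened for frontal encounters inside the
observation window; (4) the individual's motion is expressed in the
group-centered co-moving frame: positions translated so the group center is
the origin, axes rotated so the group velocity points along +x, velocities
shifted by minus the group velocity.  The norm of the relative position is
invariant under the rotation, so distance observables do not depend on the
frame choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import SkipEncounter, ValidationError
from .io import AnnotationTable, TrajectoryTable

log = logging.getLogger(__name__)

_DEGENERATE_SPEED = 1e-9


def with_velocities(traj: pd.DataFrame) -> pd.DataFrame:
    """Attach finite-difference velocities (columns vx, vy) to a single
    pedestrian's trajectory.

    Central differences on the (possibly irregular) time grid, one-sided at
    the ends; exact for uniform linear motion.  If vx/vy columns are already
    present the frame is returned unchanged, which makes downstream
    filtering idempotent.
    """
    if "vx" in traj.columns and "vy" in traj.columns:
        return traj
    if len(traj) < 2:
        raise ValidationError("need at least 2 samples to estimate velocity")
    t = traj["time"].to_numpy()
    out = traj.copy()
    out["vx"] = np.gradient(traj["x"].to_numpy(), t)
    out["vy"] = np.gradient(traj["y"].to_numpy(), t)
    return out


def filter_atypical(
    traj: pd.DataFrame,
    speed_bounds: tuple[float, float],
    min_duration: float = 1.0,
) -> list[pd.DataFrame]:
    """Split a single pedestrian's trajectory into maximal segments of
    typical walking.

    Samples whose instantaneous speed falls outside ``speed_bounds`` are
    dropped; the remaining maximal contiguous runs are returned, excluding
    runs shorter than ``min_duration`` seconds.  Velocities are computed
    once on the full trajectory so that re-filtering a segment is a no-op.
    """
    if len(traj) < 2:
        return []
    traj = with_velocities(traj)
    speed = np.hypot(traj["vx"].to_numpy(), traj["vy"].to_numpy())
    lo, hi = speed_bounds
    ok = (speed >= lo) & (speed <= hi)
    segments: list[pd.DataFrame] = []
    t = traj["time"].to_numpy()
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return segments
    # split where the kept indices are not consecutive
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        i0, i1 = idx[s], idx[e]
        if i1 == i0:
            continue
        if t[i1] - t[i0] >= min_duration:
            segments.append(traj.iloc[i0:i1 + 1].reset_index(drop=True))
    return segments


@dataclass
class GroupTrack:
    """A dyad reduced to its geometrical center.

    ``data`` columns: time, cx, cy (center, m), vx, vy (center velocity,
    m/s), sep (member separation, m; NaN for singleton "groups" used in
    individual-individual runs).
    """

    group_id: str
    class_label: str
    data: pd.DataFrame
    singleton: bool = False

    @property
    def mean_separation(self) -> float:
        return float(self.data["sep"].mean())


def build_group_track(
    member1: pd.DataFrame,
    member2: pd.DataFrame,
    group_id: str,
    class_label: str,
) -> GroupTrack:
    """Compute the dyad center track on the members' common time support.

    Member 2 is linearly interpolated onto member 1's timestamps inside the
    overlap; the center is the arithmetic midpoint and the separation the
    member distance at each common time.
    """
    t1 = member1["time"].to_numpy()
    t2 = member2["time"].to_numpy()
    lo, hi = max(t1[0], t2[0]), min(t1[-1], t2[-1])
    mask = (t1 >= lo) & (t1 <= hi)
    if mask.sum() < 2:
        raise SkipEncounter(f"group {group_id}: empty common time support")
    t = t1[mask]
    x1 = member1["x"].to_numpy()[mask]
    y1 = member1["y"].to_numpy()[mask]
    x2 = np.interp(t, t2, member2["x"].to_numpy())
    y2 = np.interp(t, t2, member2["y"].to_numpy())
    cx = 0.5 * (x1 + x2)
    cy = 0.5 * (y1 + y2)
    sep = np.hypot(x1 - x2, y1 - y2)
    data = pd.DataFrame({
        "time": t, "cx": cx, "cy": cy,
        "vx": np.gradient(cx, t), "vy": np.gradient(cy, t),
        "sep": sep,
    })
    return GroupTrack(group_id=group_id, class_label=class_label, data=data)


def singleton_track(ped: pd.DataFrame, group_id: str,
                    class_label: str = "individual") -> GroupTrack:
    """Wrap a single pedestrian as a degenerate 'group' (center = the
    pedestrian, no separation); used by the individual-individual
    comparison."""
    ped = with_velocities(ped)
    data = pd.DataFrame({
        "time": ped["time"].to_numpy(),
        "cx": ped["x"].to_numpy(), "cy": ped["y"].to_numpy(),
        "vx": ped["vx"].to_numpy(), "vy": ped["vy"].to_numpy(),
        "sep": np.nan,
    })
    return GroupTrack(group_id=group_id, class_label=class_label, data=data,
                      singleton=True)


def class_interpersonal_distance(
    group_tracks: list[GroupTrack], class_label: str
) -> float:
    """Average interpersonal distance of a social class: the unweighted mean
    over groups of each group's time-mean member separation."""
    per_group = [g.mean_separation for g in group_tracks
                 if g.class_label == class_label and not g.singleton]
    if not per_group:
        raise ValidationError(f"no groups in class {class_label!r}")
    log.debug("class %s per-group mean separations: %s", class_label, per_group)
    return float(np.mean(per_group))


@dataclass
class FrameSeries:
    """The individual's motion in the group-centered co-moving frame.

    ``pos`` is the rotated relative position (group at origin, group
    velocity along +x) and ``vel`` the rotated relative velocity
    (v_individual - v_group), both on the individual's timestamps
    restricted to the overlap with the group track.  ``pos_rel``/``vel_rel``
    are the same quantities before the rotation (translation only).  The
    distance observables are rotation-invariant and are computed from the
    unrotated series, which keeps noise in the group's heading estimate out
    of them; the rotated series serves the window test and the 2D maps.
    """

    times: np.ndarray
    pos: np.ndarray          # (n, 2) rotated
    vel: np.ndarray          # (n, 2) rotated
    pos_rel: np.ndarray      # (n, 2) translation only
    vel_rel: np.ndarray      # (n, 2) translation only
    group_speed: np.ndarray  # (n,)
    n_dropped_degenerate: int = 0


def _smooth(series: np.ndarray, times: np.ndarray, window: float) -> np.ndarray:
    """Centered moving average over ~``window`` seconds (box kernel)."""
    if window <= 0 or len(series) < 3:
        return series
    dt = np.median(np.diff(times))
    half = int(round(window / (2 * dt))) if dt > 0 else 0
    half = min(half, (len(series) - 1) // 2)
    if half < 1:
        return series
    kernel = np.ones(2 * half + 1)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


def to_group_frame(group: GroupTrack, individual: pd.DataFrame,
                   heading_smooth: float = 0.5) -> FrameSeries:
    """Transform an individual's segment into the group-centered frame.

    The group center and velocity are linearly interpolated onto the
    individual's timestamps within the overlap.  The rotation angle is
    taken from the group velocity smoothed over ``heading_smooth`` seconds:
    heading is a low-frequency quantity, and an instantaneous noisy heading
    would shake the rotated coordinates by |r| times the angle noise.
    Times at which the group speed is numerically zero (rotation undefined)
    are dropped and counted; if nothing remains the encounter is skipped.
    """
    individual = with_velocities(individual)
    tg = group.data["time"].to_numpy()
    ti = individual["time"].to_numpy()
    mask = (ti >= tg[0]) & (ti <= tg[-1])
    if mask.sum() < 2:
        raise SkipEncounter("no overlapping time support with group track")
    t = ti[mask]
    gx = np.interp(t, tg, group.data["cx"].to_numpy())
    gy = np.interp(t, tg, group.data["cy"].to_numpy())
    gvx = np.interp(t, tg, group.data["vx"].to_numpy())
    gvy = np.interp(t, tg, group.data["vy"].to_numpy())
    gspeed = np.hypot(gvx, gvy)
    good = gspeed > _DEGENERATE_SPEED
    n_dropped = int((~good).sum())
    if good.sum() < 2:
        raise SkipEncounter("group stationary throughout overlap")
    t, gx, gy, gvx, gvy, gspeed = (a[good] for a in (t, gx, gy, gvx, gvy, gspeed))

    ix = individual["x"].to_numpy()[mask][good]
    iy = individual["y"].to_numpy()[mask][good]
    ivx = individual["vx"].to_numpy()[mask][good]
    ivy = individual["vy"].to_numpy()[mask][good]

    rx, ry = ix - gx, iy - gy
    dvx, dvy = ivx - gvx, ivy - gvy
    hx = _smooth(gvx, t, heading_smooth)
    hy = _smooth(gvy, t, heading_smooth)
    hnorm = np.hypot(hx, hy)
    hnorm[hnorm == 0] = 1.0
    cos_t, sin_t = hx / hnorm, hy / hnorm  # rotate by -heading
    pos = np.column_stack([cos_t * rx + sin_t * ry, -sin_t * rx + cos_t * ry])
    vel = np.column_stack([cos_t * dvx + sin_t * dvy, -sin_t * dvx + cos_t * dvy])
    return FrameSeries(times=t, pos=pos, vel=vel,
                       pos_rel=np.column_stack([rx, ry]),
                       vel_rel=np.column_stack([dvx, dvy]),
                       group_speed=gspeed,
                       n_dropped_degenerate=n_dropped)


@dataclass
class Encounter:
    """One window entry of one individual against one group."""

    encounter_id: str
    group_id: str
    individual_id: str
    class_label: str
    frame: FrameSeries
    entry_index: int
    exit_index: int          # last consecutive in-window sample
    angle_at_entry: float    # degrees between world-frame velocities
    begins_inside: bool = False
    flags: list = field(default_factory=list)

    @property
    def t_entry(self) -> float:
        return float(self.frame.times[self.entry_index])


def _entries(inside: np.ndarray, times: np.ndarray, merge_gap: float = 1.0,
             min_duration: float = 0.25) -> list[tuple[int, int, bool]]:
    """Return (entry_index, exit_index, begins_inside) for each in-window
    run.

    Runs separated by less than ``merge_gap`` seconds are merged (positional
    noise flickers the in-window test at the boundary); runs shorter than
    ``min_duration`` seconds are dropped.  Longer gaps are genuine
    re-entries and stay separate encounters.
    """
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    raw = [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
    merged = [raw[0]]
    for i0, i1 in raw[1:]:
        if times[i0] - times[merged[-1][1]] < merge_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return [(i0, i1, bool(i0 == 0)) for i0, i1 in merged
            if times[i1] - times[i0] >= min_duration]


def select_frontal_encounters(
    group: GroupTrack,
    individual: pd.DataFrame,
    individual_id: str,
    config: RunConfig,
) -> list[Encounter]:
    """Identify frontal window entries of an individual against a group.

    An encounter is retained when the individual's group-frame position
    enters the square window ``[-W, W]^2`` and the angle between the group
    and individual world-frame velocities at entry is at least
    ``frontal_angle_min`` degrees (opposing headings).  Each maximal
    in-window run is a separate encounter; runs that start already inside
    the window are flagged.
    """
    individual = with_velocities(individual)
    try:
        frame = to_group_frame(group, individual)
    except SkipEncounter:
        return []
    W = config.window_half_width
    inside = (np.abs(frame.pos[:, 0]) <= W) & (np.abs(frame.pos[:, 1]) <= W)
    encounters = []
    tg = group.data["time"].to_numpy()
    for n, (i0, i1, begins_inside) in enumerate(
            _entries(inside, frame.times, config.window_merge_gap,
                     config.min_inside_duration)):
        t_entry = frame.times[i0]
        gvx = np.interp(t_entry, tg, group.data["vx"].to_numpy())
        gvy = np.interp(t_entry, tg, group.data["vy"].to_numpy())
        j = int(np.searchsorted(individual["time"].to_numpy(), t_entry))
        j = min(j, len(individual) - 1)
        ivx = individual["vx"].iloc[j]
        ivy = individual["vy"].iloc[j]
        ng, ni = np.hypot(gvx, gvy), np.hypot(ivx, ivy)
        if ng < _DEGENERATE_SPEED or ni < _DEGENERATE_SPEED:
            continue
        cosang = np.clip((gvx * ivx + gvy * ivy) / (ng * ni), -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cosang)))
        if angle < config.frontal_angle_min:
            continue
        flags = ["begins_inside"] if begins_inside else []
        encounters.append(Encounter(
            encounter_id=f"{group.group_id}~{individual_id}~{n}",
            group_id=group.group_id,
            individual_id=individual_id,
            class_label=group.class_label,
            frame=frame,
            entry_index=i0,
            exit_index=i1,
            angle_at_entry=angle,
            begins_inside=begins_inside,
            flags=flags,
        ))
    return encounters
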