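"""Per-encounter scattering observables.

Under the straight-line null hypothesis, an individual that does not react
to the group keeps moving along its relative velocity at window entry; the
distance of that line from the group center is the straight-line distance
``r_b`` (the analogue of the impact parameter in two-body scattering).  The
distance actually attained is the observed minimum distance ``r_0`` at the
closest-approach time ``t_c``, estimated below sampling resolution by
linearly extrapolating each sample with its velocity.  Any excess of
``r_0`` over ``r_b`` is attributed to collision avoidance.

Distances come in meters or scaled by the class-average interpersonal
distance ``d`` (written with a bar in the field's notation); an individual
with scaled minimum distance below 1 passes closer to the dyad center than
the dyad members are to each other, i.e. intrudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateVelocity, NoEncounter
from .preprocess import Encounter, FrameSeries, GroupTrack

__all__ = [
    "EncounterObservables", "entry_time", "straight_line_distance",
    "min_distance", "scale", "member_center_distance", "compute_observables",
]


@dataclass
class EncounterObservables:
    encounter_id: str
    class_label: str
    t_prime: float
    r_b: float
    r_0: float
    t_c: float
    entry_speed: float
    rbar_b: float = np.nan
    rbar_0: float = np.nan
    n_velocity_samples: int = 0
    flags: list = field(default_factory=list)


def entry_time(frame: FrameSeries, W: float) -> tuple[float, bool]:
    """First time the individual is inside the square window ``[-W, W]^2``.

    Returns ``(t_prime, begins_inside)``; ``begins_inside`` is set when the
    series never starts outside the window.  Raises :class:`NoEncounter` if
    the individual never enters.
    """
    inside = (np.abs(frame.pos[:, 0]) <= W) & (np.abs(frame.pos[:, 1]) <= W)
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        raise NoEncounter("individual never enters the observation window")
    return float(frame.times[idx[0]]), bool(idx[0] == 0)


def straight_line_distance(
    frame: FrameSeries, t_prime: float, n_avg: int = 4
) -> tuple[float, int]:
    """Distance of the undisturbed straight path from the group center.

    ``r_b = |r(t') x v_mean| / |v_mean|`` where ``v_mean`` averages the
    ``n_avg`` consecutive relative-velocity samples ending at the entry
    instant (fewer if the series is shorter — the count actually used is
    returned).  The cross product is the scalar 2D cross.  The computation
    uses the unrotated relative series: the quantity is invariant under the
    frame rotation, and evaluating it before the rotation keeps group
    heading-estimate noise out of it.  Raises :class:`DegenerateVelocity`
    when the averaged velocity vanishes.
    """
    i = int(np.searchsorted(frame.times, t_prime))
    i = min(i, len(frame.times) - 1)
    lo = max(0, i - n_avg + 1)
    v = frame.vel_rel[lo:i + 1].mean(axis=0)
    n_used = i + 1 - lo
    speed = float(np.hypot(*v))
    if speed < 1e-12:
        raise DegenerateVelocity("zero averaged relative velocity at entry")
    r = frame.pos_rel[i]
    cross = abs(r[0] * v[1] - r[1] * v[0])
    return float(cross / speed), n_used


def min_distance(
    times: np.ndarray, pos: np.ndarray, vel: np.ndarray
) -> tuple[float, float, bool]:
    """Observed minimum distance and closest-approach time.

    Candidates are the sampled distances and, on each inter-sample interval
    ``[t_k, t_{k+1})``, the closed-form minimum of the linear model
    ``r(t) = r(t_k) + (t - t_k) v(t_k)`` (the perpendicular-foot projection,
    clamped to the interval).  Ties resolve to the earliest time.  The third
    return value flags a minimum attained at the final sample (possible
    censoring at window exit).
    """
    d = np.hypot(pos[:, 0], pos[:, 1])
    best_r = float(d[0])
    best_t = float(times[0])
    for k in range(len(times)):
        if d[k] < best_r:
            best_r, best_t = float(d[k]), float(times[k])
        if k + 1 < len(times):
            v = vel[k]
            v2 = v[0] ** 2 + v[1] ** 2
            if v2 > 0:
                dt_star = -(pos[k, 0] * v[0] + pos[k, 1] * v[1]) / v2
                span = times[k + 1] - times[k]
                if dt_star > 0.0:
                    # projection clamped to the interval; at the right edge
                    # the segment model (not the next sample) is evaluated
                    dt_c = min(dt_star, span)
                    p = pos[k] + dt_c * v
                    r_star = float(np.hypot(*p))
                    if r_star < best_r:
                        best_r, best_t = r_star, float(times[k] + dt_c)
    at_end = bool(best_t >= float(times[-1]))
    return best_r, best_t, at_end


def scale(value: float, d_class: float) -> float:
    """Express a metric distance in interpersonal-distance units."""
    if d_class <= 0:
        raise ConfigurationError("class interpersonal distance must be > 0")
    return value / d_class


def member_center_distance(group: GroupTrack, d_class: float) -> float:
    """Scaled mean distance of a dyad member from the group center.

    Each member sits at half the instantaneous separation from the
    geometrical center, so this is the time average of ``sep / 2`` divided
    by the class interpersonal distance; for a dyad holding exactly the
    class separation it equals 0.5, which motivates the secondary intrusion
    threshold.
    """
    if d_class <= 0:
        raise ConfigurationError("class interpersonal distance must be > 0")
    sep = group.data["sep"].to_numpy()
    return float(np.mean(sep / 2.0) / d_class)


def compute_observables(
    encounter: Encounter,
    d_class: float,
    W: float,
    n_avg: int = 4,
) -> EncounterObservables:
    """Evaluate all observables for one encounter.

    ``t'`` is taken from the encounter's entry index; ``r_b`` uses the full
    frame series (velocity samples before entry are available), while the
    minimum distance is searched over the in-window run only, so that
    ``t_c >= t'`` by construction.
    """
    frame = encounter.frame
    i0, i1 = encounter.entry_index, encounter.exit_index
    t_prime = float(frame.times[i0])
    r_b, n_used = straight_line_distance(frame, t_prime, n_avg=n_avg)
    sl = slice(i0, i1 + 1)
    r_0, t_c, at_end = min_distance(frame.times[sl], frame.pos_rel[sl],
                                    frame.vel_rel[sl])
    flags = list(encounter.flags)
    if at_end:
        flags.append("min_at_exit")
    if n_used < n_avg:
        flags.append("short_velocity_average")
    return EncounterObservables(
        encounter_id=encounter.encounter_id,
        class_label=encounter.class_label,
        t_prime=t_prime,
        r_b=r_b,
        r_0=r_0,
        t_c=t_c,
        entry_speed=float(np.hypot(*frame.vel_rel[i0])),
        rbar_b=scale(r_b, d_class),
        rbar_0=scale(r_0, d_class),
        n_velocity_samples=n_used,
        flags=flags,
    )
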