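"""Estimation of the collision-avoidance potential.

For a conservative central repulsion, energy and angular-momentum
conservation give the potential value attained at closest approach in terms
of the impact parameter and the closest-approach distance.  Dropping the
constant kinetic-energy scale (relative speeds are nearly constant across
encounters and all masses are set to one) leaves the dimensionless probe

    U'(r = r_0) = (r_0**2 - r_b**2) / r_0**2,

which is evaluated on the binned data: the straight-line distance is
quantized, the mean minimum distance computed per bin, and one (r_0, U')
point emitted per non-empty bin.  Since the kinetic term is held fixed,
only values U' < 1 are probeable.  Power-law ``k / r**beta`` and
exponential ``a * exp(-c r)`` forms are then fitted by nonlinear least
squares to extrapolate beyond the probed range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)


def potential_probe(r_0: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """The dimensionless collision-avoidance potential probe
    ``(r_0**2 - r_b**2) / r_0**2``; bounded above by 1, equal to 0 when the
    motion is straight (r_0 = r_b)."""
    r_0 = np.asarray(r_0, float)
    r_b = np.asarray(r_b, float)
    return (r_0 ** 2 - r_b ** 2) / r_0 ** 2


def potential_points(binned: pd.DataFrame, representative: str = "mean",
                     max_r: float | None = None) -> pd.DataFrame:
    """Probe the potential on binned statistics.

    One point per non-empty (class, bin): U' evaluated at the bin's mean
    minimum distance, using as straight-line representative either the
    within-bin mean (default) or the bin midpoint.  The standard errors of
    the two bin means are propagated to a 1-sigma uncertainty ``u_err`` of
    the probe (first-order), which the fitters use as weights.  Points with
    U' < 0 (possible under environment bias) are retained but flagged; bins
    whose mean minimum distance is zero are skipped with a reason.

    ``max_r`` (typically the window half-width in the same units as the
    distances) marks points as ``censored`` when either distance exceeds
    it: an undisturbed path with straight-line distance beyond the window
    half-width can only clip the window near a corner, so its closest
    approach is truncated by the window boundary rather than measured.
    Censored points are kept in the table but skipped by the fitters.
    """
    rows = []
    for _, row in binned.iterrows():
        if row["n"] == 0:
            continue
        r0 = row["mean_r0"]
        rb = row["mean_rb"] if representative == "mean" else row["bin_mid"]
        if not np.isfinite(r0) or r0 == 0:
            log.info("potential point skipped for bin [%s, %s): mean r0 = 0",
                     row["bin_lo"], row["bin_hi"])
            continue
        u = float(potential_probe(r0, rb))
        s0 = row.get("sem_r0", np.nan)
        sb = row.get("sem_rb", np.nan)
        cov = row.get("cov_means", 0.0)
        if np.isfinite(s0) and np.isfinite(sb):
            # dU/dr0 = +2 rb^2 / r0^3, dU/drb = -2 rb / r0^2; the two bin
            # means are positively correlated, which cancels part of the
            # variance
            a = 2 * rb ** 2 / r0 ** 3
            b = 2 * rb / r0 ** 2
            var = a * a * s0 * s0 + b * b * sb * sb
            if np.isfinite(cov):
                var -= 2 * a * b * cov
            u_err = float(np.sqrt(max(var, 1e-10)))
        else:
            u_err = np.nan
        flags = []
        if u < 0:
            flags.append("negative")
        if max_r is not None and (rb > max_r or r0 > max_r):
            flags.append("censored")
        rows.append({
            "class_label": row["class_label"],
            "bin_lo": row["bin_lo"], "bin_hi": row["bin_hi"],
            "r": float(r0), "r_err": float(s0) if np.isfinite(s0) else np.nan,
            "u": u, "u_err": u_err, "n": int(row["n"]),
            "flag": ";".join(flags),
        })
    return pd.DataFrame(rows,
                        columns=["class_label", "bin_lo", "bin_hi", "r",
                                 "r_err", "u", "u_err", "n", "flag"])


@dataclass
class PotentialFit:
    class_label: str
    model: str                     # "power" or "exponential"
    params: tuple[float, float]    # (k, beta) or (a, c)
    stderr: tuple[float, float]
    residual_norm: float
    n_points: int
    distance_units: str = "scaled"
    converged: bool = True
    flags: list = field(default_factory=list)

    def predict(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        p, q = self.params
        if self.model == "power":
            return p / r ** q
        return p * np.exp(-q * r)


def _usable(points: pd.DataFrame, include_negative: bool) -> pd.DataFrame:
    pts = points[np.isfinite(points["u"]) & (points["r"] > 0)]
    if "flag" in pts.columns:
        pts = pts[~pts["flag"].fillna("").str.contains("censored")]
    if not include_negative:
        pts = pts[pts["u"] >= 0]
    return pts


#: systematic error floor for the probe, as a fraction of its dynamic
#: range: the probe carries model systematics (finite-window truncation of
#: the potential, quantization, Jensen bias of the squared bin means) that
#: the purely statistical bin-mean errors do not see, so points are never
#: trusted more tightly than this
SYSTEMATIC_FLOOR_FRACTION = 0.05


def _sigma(pts: pd.DataFrame) -> np.ndarray | None:
    """Per-point 1-sigma weights for the fit: statistical bin-mean error
    combined with a systematic floor; None when uncertainties are
    unavailable."""
    if "u_err" not in pts.columns:
        return None
    err = pts["u_err"].to_numpy(float)
    if not np.isfinite(err).all() or (err <= 0).any():
        return None
    floor = SYSTEMATIC_FLOOR_FRACTION * float(np.abs(pts["u"]).max())
    return np.hypot(err, max(floor, 1e-4))


def _fit_curve(fcn_cf, pts: pd.DataFrame, p0: tuple[float, float],
               bounds) -> tuple[tuple, tuple, bool, list]:
    """Fit a two-parameter curve to probed points.

    Weighted nonlinear least squares; per-point uncertainties (bin-mean
    standard errors combined with the systematic floor) enter as sigma.
    Exact points (no uncertainties) use unweighted least squares, which
    recovers noiseless parameters to machine precision.
    """
    sy = _sigma(pts)
    r = pts["r"].to_numpy(float)
    u = pts["u"].to_numpy(float)
    kwargs = {}
    if sy is not None:
        kwargs = {"sigma": sy}
    try:
        popt, pcov = curve_fit(fcn_cf, r, u, p0=p0, bounds=bounds,
                               maxfev=10000, **kwargs)
        return (tuple(float(v) for v in popt),
                tuple(float(v) for v in np.sqrt(np.diag(pcov))),
                True, [])
    except RuntimeError:
        return (tuple(p0), (np.nan, np.nan), False,
                ["non_converged_initializer_estimate"])


def fit_power_law(points: pd.DataFrame, class_label: str = "",
                  distance_units: str = "scaled",
                  include_negative: bool = True) -> PotentialFit | None:
    """Fit ``U' = k / r**beta`` to probed points by nonlinear least squares.

    Initialization comes from a log-log linear regression on the strictly
    positive points.  Negative-U' points (noise around a small positive
    tail) are kept by default: dropping data by sign censors the noise
    asymmetrically and flattens the fitted decay.  Returns None when fewer
    than 3 usable points remain; an all-zero probe yields a degenerate
    k = 0 fit.
    """
    pts = _usable(points, include_negative)
    if len(pts) < 3:
        log.info("power-law fit skipped (%d usable points)", len(pts))
        return None
    r = pts["r"].to_numpy(float)
    u = pts["u"].to_numpy(float)
    if np.all(u == 0):
        return PotentialFit(class_label, "power", (0.0, 1.0), (np.nan, np.nan),
                            0.0, len(pts), distance_units, converged=True,
                            flags=["degenerate_zero"])
    pos = u > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(r[pos]), np.log(u[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (max(u.max(), 1e-3), 2.0)
    p0 = (max(p0[0], 1e-8), min(max(p0[1], 0.1), 10.0))
    params, stderr, converged, flags = _fit_curve(
        lambda rr, k, b: k / rr ** b,
        pts, p0, ([0.0, 1e-3], [np.inf, 20.0]))
    resid = float(np.linalg.norm(params[0] / r ** params[1] - u))
    return PotentialFit(class_label, "power", params, stderr, resid, len(pts),
                        distance_units, converged, flags)


def fit_exponential(points: pd.DataFrame, class_label: str = "",
                    distance_units: str = "scaled",
                    include_negative: bool = True) -> PotentialFit | None:
    """Fit ``U' = a * exp(-c * r)``; initialization from a log-linear
    regression on the strictly positive points.  Same point-selection rules
    as the power-law fit."""
    pts = _usable(points, include_negative)
    if len(pts) < 3:
        log.info("exponential fit skipped (%d usable points)", len(pts))
        return None
    r = pts["r"].to_numpy(float)
    u = pts["u"].to_numpy(float)
    if np.all(u == 0):
        return PotentialFit(class_label, "exponential", (0.0, 1.0),
                            (np.nan, np.nan), 0.0, len(pts), distance_units,
                            converged=True, flags=["degenerate_zero"])
    pos = u > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(r[pos], np.log(u[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (max(u.max(), 1e-3), 1.0)
    p0 = (max(p0[0], 1e-8), min(max(p0[1], 1e-3), 20.0))
    params, stderr, converged, flags = _fit_curve(
        lambda rr, a, c: a * np.exp(-c * rr),
        pts, p0, ([0.0, 0.0], [np.inf, 50.0]))
    resid = float(np.linalg.norm(params[0] * np.exp(-params[1] * r) - u))
    return PotentialFit(class_label, "exponential", params, stderr, resid,
                        len(pts), distance_units, converged, flags)


def individual_individual_pipeline(trajectories, config,
                                   exclude_ids: set[str] = frozenset()):
    """Potential analysis for individual-individual encounters.

    Every unordered pair of non-group pedestrians is screened, with the
    lexicographically first pedestrian playing the group-center role (the
    relative distance is symmetric under the swap, so the choice does not
    affect the observables).  All distances are kept in meters — no
    interpersonal-distance scaling applies to individuals — and the usual
    chain (frontal selection, observables, binning, potential probe, fits)
    is run with a single "individual" class.

    Returns a dict with observables, binned stats, probed points and fits.
    """
    from .exceptions import DegenerateVelocity, EmptyAnalysisError
    from .observables import compute_observables
    from .preprocess import (filter_atypical, select_frontal_encounters,
                             singleton_track)
    from .analysis import bin_pairs

    segments = {}
    for pid in trajectories.pedestrian_ids:
        if pid in exclude_ids:
            continue
        segs = filter_atypical(trajectories.pedestrian(pid),
                               config.speed_bounds,
                               config.min_segment_duration)
        if segs:
            segments[pid] = segs

    pids = sorted(segments)
    rows = []
    for a_idx, target_id in enumerate(pids):
        for other_id in pids[a_idx + 1:]:
            for i, tseg in enumerate(segments[target_id]):
                track = singleton_track(
                    tseg, f"{target_id}#{i}", class_label="individual")
                for k, seg in enumerate(segments[other_id]):
                    if (seg["time"].iloc[-1] < track.data["time"].iloc[0]
                            or seg["time"].iloc[0] > track.data["time"].iloc[-1]):
                        continue
                    iid = other_id if k == 0 else f"{other_id}#{k}"
                    for enc in select_frontal_encounters(track, seg, iid, config):
                        try:
                            obs = compute_observables(
                                enc, 1.0, config.window_half_width,
                                n_avg=config.velocity_averaging_samples)
                        except DegenerateVelocity:
                            continue
                        rows.append({
                            "encounter_id": obs.encounter_id,
                            "class_label": "individual",
                            "t_prime": obs.t_prime, "r_b": obs.r_b,
                            "r_0": obs.r_0, "t_c": obs.t_c,
                            "entry_speed": obs.entry_speed,
                            "flags": ";".join(obs.flags),
                        })
    if not rows:
        raise EmptyAnalysisError("no individual-individual frontal encounters")
    obs_df = pd.DataFrame(rows)
    binned = bin_pairs(obs_df, config.bin_width, rb_col="r_b", r0_col="r_0")
    points = potential_points(binned, representative=config.rb_representative,
                              max_r=config.window_half_width)
    fits = [f for f in (
        fit_power_law(points, "individual", distance_units="meters"),
        fit_exponential(points, "individual", distance_units="meters"),
    ) if f is not None]
    return {"observables": obs_df, "binned": binned, "points": points,
            "fits": fits}


def fits_to_frame(fits: list[PotentialFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "class_label": f.class_label, "units": f.distance_units,
            "model": f.model,
            "param1": f.params[0], "param2": f.params[1],
            "stderr1": f.stderr[0], "stderr2": f.stderr[1],
            "residual": f.residual_norm, "n_points": f.n_points,
            "converged": f.converged, "flags": ";".join(f.flags),
        })
    return pd.DataFrame(rows, columns=[
        "class_label", "units", "model", "param1", "param2", "stderr1",
        "stderr2", "residual", "n_points", "converged", "flags"])
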