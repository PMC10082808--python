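"""End-to-end orchestration: trajectories + annotations -> results bundle.

Stages: velocity estimation and atypical-motion filtering, group-track
construction, class interpersonal distances, frontal-encounter selection,
observables, the straight-line-distance calibration, binned statistics with
ANOVA, intrusion tables with chi-squared tests, density maps and potential
fits.  Every filtering stage logs (before, after) counts and the bundle
records them for reconciliation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (DensityMap, LinearCorrection, anova_per_bin, bin_pairs,
                       density_map, intrusion_table, rb_linear_correction)
from .config import RunConfig
from .exceptions import (DegenerateVelocity, EmptyAnalysisError, SkipEncounter,
                         ValidationError)
from .io import AnnotationTable, TrajectoryTable
from .observables import compute_observables
from .potential import (fit_exponential, fit_power_law, fits_to_frame,
                        potential_points)
from .preprocess import (Encounter, build_group_track, class_interpersonal_distance,
                         filter_atypical, select_frontal_encounters)

log = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    observables: pd.DataFrame
    binned: pd.DataFrame
    anova: pd.DataFrame
    intrusion: pd.DataFrame
    potential_points: pd.DataFrame
    fits: pd.DataFrame
    correction: LinearCorrection
    class_distances: dict
    cumulative_map: DensityMap
    relative_maps: dict
    stage_counts: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, png: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.observables.to_csv(outdir / "observables.csv", index=False)
        self.binned.to_csv(outdir / "binned.csv", index=False)
        self.anova.to_csv(outdir / "anova.csv", index=False)
        self.intrusion.to_csv(outdir / "intrusion.csv", index=False)
        self.potential_points.to_csv(outdir / "potential_points.csv", index=False)
        self.fits.to_csv(outdir / "potential_fits.csv", index=False)
        pd.DataFrame(
            sorted(self.class_distances.items()),
            columns=["class_label", "interpersonal_distance_m"],
        ).to_csv(outdir / "class_distances.csv", index=False)
        self.cumulative_map.to_frame().to_csv(outdir / "map_cumulative.csv")
        if png:
            self.cumulative_map.plot(outdir / "map_cumulative.png",
                                     "occupancy (normalized)")
        for label, m in sorted(self.relative_maps.items()):
            m.to_frame().to_csv(outdir / f"map_relative_{label}.csv")
            if png:
                m.plot(outdir / f"map_relative_{label}.png",
                       f"relative occupancy: {label}")
        meta = pd.DataFrame([{
            "rb_correction_slope": self.correction.slope,
            "rb_correction_intercept": self.correction.intercept,
            "rb_correction_applied": self.correction.applied,
            **{f"n_{k}": v for k, v in self.stage_counts.items()},
        }])
        meta.to_csv(outdir / "run_metadata.csv", index=False)


def extract_encounters(
    config: RunConfig,
    trajectories: TrajectoryTable,
    annotations: AnnotationTable,
):
    """Filter trajectories, build group tracks and select frontal
    encounters.  Returns (group_tracks, encounters, stage_counts)."""
    annotations.validate_against(trajectories)
    counts: dict = {}
    segments: dict[str, list[pd.DataFrame]] = {}
    n_peds = 0
    for pid in trajectories.pedestrian_ids:
        n_peds += 1
        segs = filter_atypical(trajectories.pedestrian(pid),
                               config.speed_bounds,
                               config.min_segment_duration)
        if segs:
            segments[pid] = segs
    counts["pedestrians"] = n_peds
    counts["pedestrians_after_speed_filter"] = len(segments)
    log.info("speed filter: %d -> %d pedestrians", n_peds, len(segments))

    group_members = annotations.group_members
    group_tracks = []
    n_group_candidates = 0
    for _, row in annotations.data.iterrows():
        m1 = segments.get(row["member_id_1"], [])
        m2 = segments.get(row["member_id_2"], [])
        for i, s1 in enumerate(m1):
            for j, s2 in enumerate(m2):
                n_group_candidates += 1
                gid = row["group_id"] if (i, j) == (0, 0) else f"{row['group_id']}#{i}{j}"
                try:
                    group_tracks.append(
                        build_group_track(s1, s2, gid, row["class_label"]))
                except SkipEncounter:
                    continue
    counts["group_segment_pairs"] = n_group_candidates
    counts["group_tracks"] = len(group_tracks)

    individuals = {pid: segs for pid, segs in segments.items()
                   if pid not in group_members}
    counts["individuals_after_filter"] = len(individuals)

    indiv_segments = [
        (pid if k == 0 else f"{pid}#{k}", seg,
         float(seg["time"].iloc[0]), float(seg["time"].iloc[-1]))
        for pid, segs in individuals.items() for k, seg in enumerate(segs)
    ]
    seg_lo = np.array([s[2] for s in indiv_segments])
    seg_hi = np.array([s[3] for s in indiv_segments])

    encounters: list[Encounter] = []
    for gt in group_tracks:
        g_lo = float(gt.data["time"].iloc[0])
        g_hi = float(gt.data["time"].iloc[-1])
        for j in np.flatnonzero((seg_hi >= g_lo) & (seg_lo <= g_hi)):
            iid, seg, _, _ = indiv_segments[j]
            encounters.extend(
                select_frontal_encounters(gt, seg, iid, config))
    counts["frontal_encounters"] = len(encounters)
    log.info("selected %d frontal encounters from %d group tracks",
             len(encounters), len(group_tracks))
    return group_tracks, encounters, counts


def run_pipeline(
    config: RunConfig,
    trajectories: TrajectoryTable,
    annotations: AnnotationTable,
) -> ResultsBundle:
    """Run the full analysis and return all result tables.

    Deterministic given (inputs, config, seed).  Raises
    :class:`EmptyAnalysisError` when no encounter survives filtering.
    """
    group_tracks, encounters, counts = extract_encounters(
        config, trajectories, annotations)
    if not encounters:
        raise EmptyAnalysisError("no frontal encounters after filtering")

    class_distances = {}
    for label in sorted({g.class_label for g in group_tracks}):
        class_distances[label] = class_interpersonal_distance(group_tracks, label)
    log.info("class interpersonal distances: %s", class_distances)

    rows = []
    frame_points = []
    frame_labels = []
    n_degenerate = 0
    n_begins_inside = 0
    for enc in encounters:
        if enc.begins_inside:
            # no genuine window crossing: the entry velocity (hence r_b)
            # would be measured from a point already inside the window
            n_begins_inside += 1
            continue
        d_class = class_distances[enc.class_label]
        try:
            obs = compute_observables(enc, d_class, config.window_half_width,
                                      n_avg=config.velocity_averaging_samples)
        except DegenerateVelocity:
            n_degenerate += 1
            continue
        rows.append({
            "encounter_id": obs.encounter_id, "class_label": obs.class_label,
            "group_id": enc.group_id, "individual_id": enc.individual_id,
            "t_prime": obs.t_prime, "r_b": obs.r_b, "r_0": obs.r_0,
            "t_c": obs.t_c, "entry_speed": obs.entry_speed,
            "rbar_b": obs.rbar_b, "rbar_0": obs.rbar_0,
            "angle_at_entry": enc.angle_at_entry,
            "flags": ";".join(obs.flags),
        })
        sl = slice(enc.entry_index, enc.exit_index + 1)
        pts = enc.frame.pos[sl]
        frame_points.append(pts)
        frame_labels.append(np.full(len(pts), enc.class_label))
    counts["encounters_begins_inside"] = n_begins_inside
    counts["encounters_degenerate_velocity"] = n_degenerate
    counts["encounters_with_observables"] = len(rows)
    if not rows:
        raise EmptyAnalysisError("all encounters dropped (degenerate velocity)")
    obs_df = pd.DataFrame(rows)

    if config.rb_correction:
        obs_df, correction = rb_linear_correction(
            obs_df, floor=config.rb_correction_floor)
    else:
        correction = LinearCorrection(1.0, 0.0, 0, applied=False)

    binned = bin_pairs(obs_df, config.bin_width)
    anova = anova_per_bin(obs_df, config.bin_width)
    intrusion = intrusion_table(obs_df, config.intrusion_thresholds,
                                config.bin_width)
    point_frames = []
    fits = []
    for label in sorted(obs_df["class_label"].unique()):
        sub_binned = binned[binned["class_label"] == label]
        # straight-line distances beyond the window half-width (scaled per
        # class) enter only near window corners: censored, not fitted
        sub = potential_points(sub_binned,
                               representative=config.rb_representative,
                               max_r=config.window_half_width / class_distances[label])
        point_frames.append(sub)
        for fitter in (fit_power_law, fit_exponential):
            f = fitter(sub, class_label=label, distance_units="scaled")
            if f is not None:
                fits.append(f)
    points = pd.concat(point_frames, ignore_index=True)

    W = config.window_half_width
    all_pts = np.concatenate(frame_points)
    all_labels = np.concatenate(frame_labels)
    cumulative = density_map(all_pts, (-W, W, -W, W), config.grid_cell,
                             "cumulative-normalized")
    relative = density_map(all_pts, (-W, W, -W, W), config.grid_cell,
                           "relative", class_labels=all_labels)

    # relative-speed variation, logged so the constant-kinetic-energy
    # assumption behind the potential probe can be checked
    speeds = obs_df["entry_speed"].to_numpy()
    log.info("entry relative speed: mean %.3f m/s, cv %.3f",
             speeds.mean(), speeds.std() / speeds.mean() if speeds.mean() else np.nan)

    return ResultsBundle(
        observables=obs_df, binned=binned, anova=anova, intrusion=intrusion,
        potential_points=points, fits=fits_to_frame(fits),
        correction=correction, class_distances=class_distances,
        cumulative_map=cumulative, relative_maps=relative,
        stage_counts=counts,
    )
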