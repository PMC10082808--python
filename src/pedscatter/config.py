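"""Run configuration for the collision-avoidance analysis pipeline.

All tunable analysis parameters live in :class:`RunConfig` so that a run is
fully described by (input data, config, seed).  The defaults follow the
conventions of the underlying analysis: a square observation window of
half-width 4 m around the group center, scaled-distance bins of 0.5
interpersonal-distance units, intrusion thresholds at 1 and 0.5 units, and a
10 cm density-map grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class RunConfig:
    """Parameters controlling encounter extraction and analysis.

    Attributes
    ----------
    window_half_width:
        Half-width W of the square observation window around the group
        center, in meters.  An encounter starts when the individual enters
        ``[-W, W] x [-W, W]`` in the group-centered frame.
    bin_width:
        Width of the bins used to quantize the scaled straight-line distance
        (interpersonal-distance units; meters for individual-individual runs).
    intrusion_thresholds:
        Scaled minimum-distance thresholds below which an encounter counts
        as an intrusion.
    speed_bounds:
        (min, max) walking speed in m/s; samples outside are treated as
        atypical motion (waiting, running) and removed.
    min_segment_duration:
        Shortest trajectory segment (seconds) kept after speed filtering.
    frontal_angle_min:
        Minimum angle (degrees) between the group and individual world-frame
        velocities at window entry for the encounter to count as frontal.
    velocity_averaging_samples:
        Number of consecutive relative-velocity samples, ending at the entry
        instant, averaged before computing the straight-line distance.
    grid_cell:
        Cell size (meters) of the 2D density-map histograms.
    window_merge_gap:
        In-window runs of one individual against one group separated by a
        gap shorter than this (seconds) are merged into a single encounter;
        positional noise otherwise splits a single pass at the window
        boundary.  Longer gaps count as genuine re-entries.
    min_inside_duration:
        Shortest in-window run (seconds) kept as an encounter.
    rb_correction:
        Whether to apply the linear calibration of the scaled straight-line
        distance against the scaled minimum distance in the
        large-separation regime (compensates environment-induced bias).
    rb_correction_floor:
        Lower bound of the scaled straight-line distance defining the
        calibration regime.
    rb_representative:
        Which per-bin representative of the straight-line distance the
        potential probe uses: the within-bin "mean" (default) or the bin
        "midpoint".
    rng_seed:
        Seed for every source of randomness flowing through a run.
    """

    window_half_width: float = 4.0
    bin_width: float = 0.5
    intrusion_thresholds: tuple[float, ...] = (1.0, 0.5)
    speed_bounds: tuple[float, float] = (0.5, 3.0)
    min_segment_duration: float = 1.0
    frontal_angle_min: float = 135.0
    velocity_averaging_samples: int = 4
    grid_cell: float = 0.10
    window_merge_gap: float = 1.0
    min_inside_duration: float = 0.25
    rb_correction: bool = True
    rb_correction_floor: float = 2.0
    rb_representative: str = "mean"
    rng_seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_half_width <= 0:
            raise ConfigurationError("window_half_width must be > 0")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        self.intrusion_thresholds = tuple(float(t) for t in self.intrusion_thresholds)
        if any(t <= 0 for t in self.intrusion_thresholds):
            raise ConfigurationError("intrusion thresholds must be > 0")
        lo, hi = self.speed_bounds
        if not lo < hi:
            raise ConfigurationError("speed_bounds must satisfy min < max")
        self.speed_bounds = (float(lo), float(hi))
        if self.velocity_averaging_samples < 1:
            raise ConfigurationError("velocity_averaging_samples must be >= 1")
        if self.grid_cell <= 0:
            raise ConfigurationError("grid_cell must be > 0")
        if self.rb_representative not in ("mean", "midpoint"):
            raise ConfigurationError("rb_representative must be 'mean' or 'midpoint'")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        unknown = {k: v for k, v in d.items() if k not in known}
        if unknown:
            kwargs.setdefault("extra", {}).update(unknown)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
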