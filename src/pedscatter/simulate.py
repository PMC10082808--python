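"""Synthetic encounter generator with known ground truth.

The generator produces frontal encounters between a dyad (two pedestrians
walking abreast with a class-dependent interpersonal distance) and an
individual in a straight corridor, governed by a social-force style model:

* goal attraction — each pedestrian relaxes toward a fixed desired velocity
  with time constant ``relaxation_time``;
* dyad cohesion — a spring about the target separation ``d`` keeps the two
  members together (the goal term supplies the damping);
* group-individual avoidance — a central repulsive force derived from the
  potential ``U(r) = k / r**beta`` acting along the line joining the group
  center and the individual; the individual feels the full force, the dyad
  members a reduced share (``mobility_factor``), reflecting the observation
  that groups deviate less than individuals.

With probability ``intrusion_propensity`` the avoidance force is suppressed
for the whole encounter, modeling individuals who walk straight through the
dyad.  The relaxation time is deliberately long compared to the window
crossing so that the dynamics between entry and closest approach stays
close to conservative and the ground-truth potential is recoverable through
the scattering relation; this is a design goal of the harness, not a claim
of behavioral realism.

Positions are recorded at ``sampling_period`` with additive Gaussian
observation noise; the analysis only ever sees the sampled, noisy output.
All encounters of a dataset are integrated as one vectorized batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, IntegrationError
from .io import AnnotationTable, TrajectoryTable

log = logging.getLogger(__name__)

#: minimum center-individual distance entering the force law (numerical floor)
FORCE_FLOOR = 0.05

_SUBSTEPS = 10


@dataclass
class ClassSpec:
    """Ground-truth parameters of one social class of dyads.

    ``interpersonal_distance_mean`` (m) sets the abreast separation,
    ``potential_strength``/``potential_exponent`` the repulsive potential
    ``k / r**beta`` (unit mass, so k has units m**beta * (m/s)**2), and
    ``intrusion_propensity`` the probability that an individual ignores the
    dyad and walks straight through it.
    """

    label: str
    interpersonal_distance_mean: float = 0.70
    interpersonal_distance_sd: float = 0.10
    potential_strength: float = 0.5
    potential_exponent: float = 2.0
    intrusion_propensity: float = 0.1

    def __post_init__(self) -> None:
        if self.interpersonal_distance_mean <= 0:
            raise ConfigurationError("interpersonal_distance_mean must be > 0")
        if self.potential_strength < 0:
            raise ConfigurationError("potential_strength must be >= 0")
        if self.potential_exponent <= 0:
            raise ConfigurationError("potential_exponent must be > 0")
        if not 0 <= self.intrusion_propensity <= 1:
            raise ConfigurationError("intrusion_propensity must be in [0, 1]")


@dataclass
class SimScenario:
    """Corridor geometry, kinematics and sampling of the synthetic study."""

    corridor_length: float = 12.0
    corridor_width: float = 12.0
    desired_speed_mean: float = 1.2
    desired_speed_sd: float = 0.2
    lateral_offset_max: float = 5.0
    start_gap: float = 10.0
    duration: float = 8.0
    sampling_period: float = 0.05
    position_noise_sd: float = 0.01
    relaxation_time: float = 2.0
    cohesion_strength: float = 2.0
    mobility_factor: float = 0.5
    n_encounters: int = 200
    class_mix: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "corridor_length", "corridor_width", "desired_speed_mean",
            "lateral_offset_max", "start_gap", "duration", "sampling_period",
            "relaxation_time", "cohesion_strength",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.position_noise_sd < 0 or self.desired_speed_sd < 0:
            raise ConfigurationError("noise/sd parameters must be >= 0")
        if not 0 <= self.mobility_factor <= 1:
            raise ConfigurationError("mobility_factor must be in [0, 1]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


@dataclass
class _Batch:
    """Per-encounter ground-truth draws for a vectorized integration."""

    d_target: np.ndarray      # (B,)
    v_group: np.ndarray       # (B,)
    v_indiv: np.ndarray       # (B,)
    offset: np.ndarray        # (B,)
    k_eff: np.ndarray         # (B,) 0 where intruding
    beta: np.ndarray          # (B,)
    intruded: np.ndarray      # (B,) bool
    n_group: int = 2
    with_individual: bool = True
    init_sep: np.ndarray | None = None  # dyad start separation; default d


def _draw_batch(class_spec: ClassSpec, scenario: SimScenario,
                rng: np.random.Generator, size: int,
                offset: np.ndarray | None = None,
                n_group: int = 2, with_individual: bool = True) -> _Batch:
    cs, sp = class_spec, scenario
    d = _truncated_normal(
        rng, cs.interpersonal_distance_mean, cs.interpersonal_distance_sd,
        max(0.2, cs.interpersonal_distance_mean - 3 * cs.interpersonal_distance_sd),
        cs.interpersonal_distance_mean + 3 * cs.interpersonal_distance_sd, size)
    vg = _truncated_normal(rng, sp.desired_speed_mean, sp.desired_speed_sd,
                           0.6, 2.9, size)
    vi = _truncated_normal(rng, sp.desired_speed_mean, sp.desired_speed_sd,
                           0.6, 2.9, size)
    if offset is None:
        offset = (rng.uniform(0.0, sp.lateral_offset_max, size)
                  * rng.choice([-1.0, 1.0], size))
    else:
        offset = np.broadcast_to(np.asarray(offset, float), (size,)).copy()
    intruded = rng.random(size) < cs.intrusion_propensity
    k_eff = np.where(intruded, 0.0, cs.potential_strength)
    beta = np.full(size, cs.potential_exponent)
    return _Batch(d, vg, vi, offset, k_eff, beta, intruded,
                  n_group=n_group, with_individual=with_individual)


def _integrate(batch: _Batch, scenario: SimScenario) -> np.ndarray:
    """Fixed-step Euler integration of a batch of independent encounters.

    Returns noiseless sampled positions of shape (B, n_samples, A, 2) where
    the first ``n_group`` agents are the dyad members (or single target)
    and the last one, if present, the incoming individual.
    """
    sp = scenario
    B = len(batch.d_target)
    ng = batch.n_group
    A = ng + (1 if batch.with_individual else 0)
    pos = np.zeros((B, A, 2))
    vel = np.zeros((B, A, 2))
    desired = np.zeros((B, A, 2))
    if ng == 2:
        sep0 = batch.init_sep if batch.init_sep is not None else batch.d_target
        pos[:, 0, 1] = +sep0 / 2
        pos[:, 1, 1] = -sep0 / 2
    vel[:, :ng, 0] = batch.v_group[:, None]
    desired[:, :ng, 0] = batch.v_group[:, None]
    if batch.with_individual:
        pos[:, -1, 0] = sp.start_gap
        pos[:, -1, 1] = batch.offset
        vel[:, -1, 0] = -batch.v_indiv
        desired[:, -1, 0] = -batch.v_indiv

    dt = sp.sampling_period / _SUBSTEPS
    n_samples = int(round(sp.duration / sp.sampling_period)) + 1
    out = np.empty((B, n_samples, A, 2))
    out[:, 0] = pos
    tau = sp.relaxation_time
    interacting = batch.with_individual and (batch.k_eff > 0).any()
    kb = batch.k_eff * batch.beta
    for step in range(1, (n_samples - 1) * _SUBSTEPS + 1):
        acc = (desired - vel) / tau
        if ng == 2:
            s = pos[:, 0] - pos[:, 1]
            dist = np.hypot(s[:, 0], s[:, 1])
            np.maximum(dist, 1e-12, out=dist)
            f = (-sp.cohesion_strength * (dist - batch.d_target) / dist)[:, None] * s
            acc[:, 0] += f
            acc[:, 1] -= f
        if interacting:
            center = pos[:, :ng].mean(axis=1)
            rvec = pos[:, -1] - center
            r = np.hypot(rvec[:, 0], rvec[:, 1])
            np.maximum(r, FORCE_FLOOR, out=r)
            mag = kb / r ** (batch.beta + 1)
            frep = (mag / r)[:, None] * rvec
            acc[:, -1] += frep
            acc[:, :ng] -= sp.mobility_factor * frep[:, None, :]
        vel += dt * acc
        pos += dt * vel
        if step % _SUBSTEPS == 0:
            k = step // _SUBSTEPS
            if not np.isfinite(pos).all():
                raise IntegrationError(
                    f"non-finite state at integration step {step}")
            out[:, k] = pos
    return out


def _to_tables(samples: np.ndarray, batch: _Batch, scenario: SimScenario,
               rng: np.random.Generator, encounter_ids: list[int],
               t_starts: np.ndarray) -> pd.DataFrame:
    """Sampled batch -> long trajectory frame (with observation noise)."""
    sp = scenario
    if sp.position_noise_sd > 0:
        samples = samples + rng.normal(0.0, sp.position_noise_sd, samples.shape)
    B, n_samples, A, _ = samples.shape
    ng = batch.n_group
    names = (["g1", "g2"] if ng == 2 else ["t"])
    if batch.with_individual:
        names.append("i")
    rel_times = sp.sampling_period * np.arange(n_samples)
    frames = []
    for b in range(B):
        eid = encounter_ids[b]
        times = t_starts[b] + rel_times
        for a, suffix in enumerate(names):
            frames.append(pd.DataFrame({
                "time": times,
                "id": f"e{eid}_{suffix}",
                "x": samples[b, :, a, 0],
                "y": samples[b, :, a, 1],
            }))
    return pd.concat(frames, ignore_index=True)


def _truth_frame(batch: _Batch, encounter_ids: list[int],
                 labels: list[str], k_true: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "encounter_id": [f"e{i}" for i in encounter_ids],
        "class_label": labels,
        "d": batch.d_target,
        "k_true": k_true,
        "beta_true": batch.beta,
        "offset": batch.offset,
        "intruded": batch.intruded,
        "v_group": batch.v_group,
        "v_individual": batch.v_indiv,
    })


def simulate_encounter(
    class_spec: ClassSpec,
    scenario: SimScenario,
    seed: int | np.random.Generator,
    encounter_id: int = 0,
    t_start: float = 0.0,
    with_individual: bool = True,
    group_size: int = 2,
    offset: float | None = None,
    initial_separation: float | None = None,
) -> tuple[TrajectoryTable, dict]:
    """Integrate one dyad-individual encounter and sample it.

    Returns the sampled (noisy) trajectory table of the 2 + 1 pedestrians
    and the ground-truth record (class, d, k, beta, lateral offset,
    intrusion flag, desired speeds).  ``group_size=1`` yields a single
    "target" pedestrian instead of a dyad (for individual-individual
    studies); ``with_individual=False`` drops the incoming pedestrian
    (dyad-only relaxation runs).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    off = None if offset is None else np.array([offset])
    batch = _draw_batch(class_spec, scenario, rng, 1, offset=off,
                        n_group=2 if group_size == 2 else 1,
                        with_individual=with_individual)
    if initial_separation is not None:
        batch.init_sep = np.array([float(initial_separation)])
    try:
        samples = _integrate(batch, scenario)
    except IntegrationError as exc:
        raise IntegrationError(f"{exc} (encounter {encounter_id})") from None
    data = _to_tables(samples, batch, scenario, rng, [encounter_id],
                      np.array([t_start]))
    truth = _truth_frame(batch, [encounter_id], [class_spec.label],
                         np.full(1, class_spec.potential_strength)).iloc[0].to_dict()
    table = TrajectoryTable(data, sampling_period=scenario.sampling_period)
    return table, truth


def simulate_dataset(
    scenario: SimScenario,
    class_specs: list[ClassSpec],
    seed: int,
    label_scheme: str = "custom",
) -> tuple[TrajectoryTable, AnnotationTable, pd.DataFrame]:
    """Simulate ``scenario.n_encounters`` independent encounters.

    Encounters occupy disjoint time blocks so that pairing group tracks
    with individuals by overlapping time support reconstructs the intended
    encounters without consulting the ground truth.  Class labels are drawn
    from ``scenario.class_mix`` (weights normalized; uniform over
    ``class_specs`` if empty).  All encounters of one class are integrated
    as a single vectorized batch.
    """
    if not class_specs:
        raise ConfigurationError("class_specs must not be empty")
    rng = np.random.default_rng(seed)
    by_label = {c.label: c for c in class_specs}
    if scenario.class_mix:
        labels = list(scenario.class_mix)
        missing = set(labels) - set(by_label)
        if missing:
            raise ConfigurationError(f"class_mix labels {sorted(missing)} have no spec")
        w = np.array([scenario.class_mix[l] for l in labels], dtype=float)
        if w.sum() <= 0:
            raise ConfigurationError("class_mix weights must sum to > 0")
        w = w / w.sum()
    else:
        labels = [c.label for c in class_specs]
        w = np.full(len(labels), 1.0 / len(labels))

    n = scenario.n_encounters
    assigned = [labels[j] for j in rng.choice(len(labels), size=n, p=w)]
    block = scenario.duration + 5.0
    t_starts = block * np.arange(n)

    tables, truths, annotations = [], [], []
    for label in sorted(set(assigned)):
        ids = [i for i, a in enumerate(assigned) if a == label]
        batch = _draw_batch(by_label[label], scenario, rng, len(ids))
        samples = _integrate(batch, scenario)
        tables.append(_to_tables(samples, batch, scenario, rng, ids,
                                 t_starts[ids]))
        truths.append(_truth_frame(
            batch, ids, [label] * len(ids),
            np.full(len(ids), by_label[label].potential_strength)))
    for i, label in enumerate(assigned):
        annotations.append({
            "group_id": f"e{i}_g",
            "member_id_1": f"e{i}_g1",
            "member_id_2": f"e{i}_g2",
            "class_label": label,
        })
    traj = TrajectoryTable(pd.concat(tables, ignore_index=True),
                           sampling_period=scenario.sampling_period)
    annot = AnnotationTable(pd.DataFrame(annotations), label_scheme=label_scheme,
                            label_set=frozenset(by_label))
    truth_df = (pd.concat(truths, ignore_index=True)
                .sort_values("encounter_id", key=lambda s: s.str[1:].astype(int))
                .reset_index(drop=True))
    log.info("simulated %d encounters (%d trajectory rows)",
             n, len(traj.data))
    return traj, annot, truth_df


def relation_classes() -> list[ClassSpec]:
    """Default social-relation classes (couples, friends, family,
    colleagues) with qualitatively ordered avoidance strengths: strongly
    bonded dyads walk closer, repel individuals more and are intruded on
    less."""
    return [
        ClassSpec("couples", 0.60, 0.08, potential_strength=0.9,
                  intrusion_propensity=0.02),
        ClassSpec("friends", 0.70, 0.10, potential_strength=0.7,
                  intrusion_propensity=0.05),
        ClassSpec("family", 0.75, 0.12, potential_strength=0.35,
                  intrusion_propensity=0.20),
        ClassSpec("colleagues", 0.80, 0.10, potential_strength=0.30,
                  intrusion_propensity=0.15),
    ]


def intensity_classes() -> list[ClassSpec]:
    """Default interaction-intensity classes 0-3: avoidance strength grows
    and intrusion propensity falls with intensity."""
    return [
        ClassSpec("0", 0.85, 0.12, potential_strength=0.15,
                  intrusion_propensity=0.30),
        ClassSpec("1", 0.78, 0.10, potential_strength=0.35,
                  intrusion_propensity=0.15),
        ClassSpec("2", 0.70, 0.10, potential_strength=0.60,
                  intrusion_propensity=0.08),
        ClassSpec("3", 0.65, 0.08, potential_strength=0.90,
                  intrusion_propensity=0.03),
    ]
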