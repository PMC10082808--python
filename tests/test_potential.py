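import numpy as np
import pandas as pd
import pytest

from pedscatter import (RunConfig, bin_pairs, fit_exponential, fit_power_law,
                        individual_individual_pipeline, potential_points,
                        potential_probe)
from pedscatter.io import TrajectoryTable
from pedscatter.simulate import ClassSpec, SimScenario, simulate_encounter


def points_frame(r, u, label="c"):
    return pd.DataFrame({"class_label": label, "bin_lo": 0.0, "bin_hi": 0.5,
                         "r": np.asarray(r, float), "u": np.asarray(u, float),
                         "n": 10, "flag": ""})


@pytest.mark.parametrize("r0,rb,expected", [
    (2.0, 2.0, 0.0),    # straight motion probes zero
    (1.0, 0.0, 1.0),    # head-on limit
    (2.0, 1.0, 0.75),
])
def test_probe_values(r0, rb, expected):
    assert potential_probe(r0, rb) == pytest.approx(expected)


def test_probe_bound_on_exhaustive_grid():
    rb, r0 = np.meshgrid(np.linspace(0, 10, 301), np.linspace(1e-3, 10, 301))
    u = potential_probe(r0, rb)
    assert np.max(u) <= 1.0
    assert np.all(u[rb > 0] < 1.0)


def test_potential_points_from_binned():
    obs = pd.DataFrame({"class_label": "c",
                        "rbar_b": [0.2, 0.3, 0.7, 0.8],
                        "rbar_0": [1.0, 1.2, 1.3, 1.5]})
    binned = bin_pairs(obs, 0.5)
    pts = potential_points(binned)
    assert len(pts) == 2
    first = pts.iloc[0]
    assert first["r"] == pytest.approx(1.1)
    assert first["u"] == pytest.approx((1.1 ** 2 - 0.25 ** 2) / 1.1 ** 2)


def test_potential_points_midpoint_representative():
    obs = pd.DataFrame({"class_label": "c", "rbar_b": [0.2, 0.3],
                        "rbar_0": [1.0, 1.2]})
    pts = potential_points(bin_pairs(obs, 0.5), representative="midpoint")
    assert pts.iloc[0]["u"] == pytest.approx((1.1 ** 2 - 0.25 ** 2) / 1.1 ** 2)


def test_potential_points_censoring():
    obs = pd.DataFrame({"class_label": "c", "rbar_b": [0.2, 4.6],
                        "rbar_0": [1.0, 4.8]})
    pts = potential_points(bin_pairs(obs, 0.5), max_r=4.0)
    assert "censored" in pts.iloc[1]["flag"] and pts.iloc[0]["flag"] == ""


def test_power_law_exact_recovery():
    r = np.array([1.0, 2.0, 4.0])
    fit = fit_power_law(points_frame(r, 2.0 / r ** 2))
    k, beta = fit.params
    assert k == pytest.approx(2.0, abs=1e-9)
    assert beta == pytest.approx(2.0, abs=1e-9)
    assert fit.converged


def test_power_law_noisy_replicates():
    """1% multiplicative noise: the exponent stays within 10% of truth in
    at least 95% of replicates."""
    rng = np.random.default_rng(17)
    r = np.array([0.8, 1.0, 1.5, 2.0, 3.0, 4.0])
    hits = 0
    for _ in range(100):
        u = (2.0 / r ** 2) * (1 + 0.01 * rng.normal(size=r.size))
        beta = fit_power_law(points_frame(r, u)).params[1]
        hits += 1.8 <= beta <= 2.2
    assert hits >= 95


def test_power_law_all_zero_degenerate():
    fit = fit_power_law(points_frame([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]))
    assert fit.params[0] == 0.0
    assert "degenerate_zero" in fit.flags


def test_fit_skipped_below_three_points():
    assert fit_power_law(points_frame([1.0], [0.5])) is None
    assert fit_exponential(points_frame([1.0, 2.0], [0.5, 0.2])) is None


def test_exponential_exact_recovery():
    r = np.array([0.5, 1.0, 2.0])
    fit = fit_exponential(points_frame(r, np.exp(-r)))
    a, c = fit.params
    assert a == pytest.approx(1.0, abs=1e-9)
    assert c == pytest.approx(1.0, abs=1e-9)


def test_model_discrimination_by_residual():
    """On noiseless power-law data the exponential fit leaves a larger
    residual than the generating form, and vice versa."""
    r = np.linspace(0.5, 4.0, 8)
    u_pow = 1.5 / r ** 2
    assert (fit_power_law(points_frame(r, u_pow)).residual_norm
            < fit_exponential(points_frame(r, u_pow)).residual_norm)
    u_exp = 1.5 * np.exp(-1.2 * r)
    assert (fit_exponential(points_frame(r, u_exp)).residual_norm
            < fit_power_law(points_frame(r, u_exp)).residual_norm)


def test_fit_invariant_to_point_order():
    rng = np.random.default_rng(23)
    r = np.array([0.8, 1.2, 1.7, 2.5, 3.5])
    u = 1.2 / r ** 1.8 + rng.normal(0, 0.01, r.size)
    base = fit_power_law(points_frame(r, u)).params
    perm = rng.permutation(r.size)
    shuffled = fit_power_law(points_frame(r[perm], u[perm])).params
    assert base == pytest.approx(shuffled, rel=1e-6)


def _pair_dataset(k, n=40, seed=3, offsets=None):
    """Concatenate individual-individual encounters (one walker is the
    'target'), each in its own time block."""
    spec = ClassSpec("ii", 0.7, 0.0, potential_strength=k,
                     intrusion_propensity=0.0)
    scenario = SimScenario(position_noise_sd=0.005, lateral_offset_max=3.5)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n):
        off = None if offsets is None else offsets[i]
        table, _ = simulate_encounter(spec, scenario, rng, encounter_id=i,
                                      t_start=i * 13.0, group_size=1,
                                      offset=off)
        frames.append(table.data)
    return TrajectoryTable(pd.concat(frames, ignore_index=True),
                           sampling_period=scenario.sampling_period)


def test_individual_individual_repulsion_decreasing():
    traj = _pair_dataset(k=0.8, n=60)
    out = individual_individual_pipeline(traj, RunConfig(rb_correction=False))
    pts = out["points"]
    usable = pts[~pts.flag.str.contains("censored")]
    # potential probed at small distances exceeds the tail
    near = usable[usable.r < 1.5]["u"].mean()
    far = usable[usable.r > 2.5]["u"].mean()
    assert near > far
    assert len(out["fits"]) == 2
    power = [f for f in out["fits"] if f.model == "power"][0]
    assert power.distance_units == "meters"
    assert power.params[0] > 0


def test_individual_individual_straight_pair_null():
    spec = ClassSpec("ii", 0.7, 0.0, potential_strength=0.0,
                     intrusion_propensity=0.0)
    scenario = SimScenario(position_noise_sd=0.0)
    rng = np.random.default_rng(5)
    frames = []
    for i in range(10):
        table, _ = simulate_encounter(spec, scenario, rng, encounter_id=i,
                                      t_start=i * 13.0, group_size=1)
        frames.append(table.data)
    traj = TrajectoryTable(pd.concat(frames, ignore_index=True),
                           sampling_period=scenario.sampling_period)
    out = individual_individual_pipeline(traj, RunConfig())
    assert np.abs(out["observables"]["r_0"]
                  - out["observables"]["r_b"]).max() < 1e-6


def test_individual_individual_target_swap_symmetric():
    """Swapping which pedestrian plays the group-center role leaves the
    distance observables unchanged (|r| is symmetric)."""
    from pedscatter.observables import compute_observables
    from pedscatter.preprocess import (select_frontal_encounters,
                                       singleton_track, with_velocities)
    spec = ClassSpec("ii", 0.7, 0.0, potential_strength=0.5,
                     intrusion_propensity=0.0)
    scenario = SimScenario(position_noise_sd=0.0)
    table, _ = simulate_encounter(spec, scenario, seed=8, group_size=1,
                                  offset=0.8)
    cfg = RunConfig()
    a = with_velocities(table.pedestrian("e0_t"))
    b = with_velocities(table.pedestrian("e0_i"))
    obs = {}
    for name, (target, other) in {"ab": (a, b), "ba": (b, a)}.items():
        track = singleton_track(target, "t")
        enc = select_frontal_encounters(track, other, "o", cfg)[0]
        obs[name] = compute_observables(enc, 1.0, cfg.window_half_width)
    assert obs["ab"].r_0 == pytest.approx(obs["ba"].r_0, abs=1e-6)
    assert obs["ab"].r_b == pytest.approx(obs["ba"].r_b, abs=1e-3)
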