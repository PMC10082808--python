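import numpy as np
import pandas as pd
import pytest

from pedscatter import (RunConfig, build_group_track,
                        class_interpersonal_distance, filter_atypical,
                        select_frontal_encounters, to_group_frame,
                        with_velocities)
from pedscatter.exceptions import SkipEncounter, ValidationError
from pedscatter.preprocess import GroupTrack
from tests.conftest import straight_walker

BOUNDS = (0.5, 3.0)


def test_standing_still_removed():
    df = straight_walker(0, 0, 0.0, 0.0)
    assert filter_atypical(df, BOUNDS) == []


def test_constant_walk_one_segment():
    df = straight_walker(0, 0, 1.2, 0.0)
    segs = filter_atypical(df, BOUNDS)
    assert len(segs) == 1
    assert len(segs[0]) == len(df)


def test_walk_stop_walk_two_segments():
    dt = 0.05
    t = np.arange(0, 9, dt)
    x = np.piecewise(
        t, [t < 3, (t >= 3) & (t < 6), t >= 6],
        [lambda s: 1.2 * s, lambda s: 3.6, lambda s: 3.6 + 1.2 * (s - 6)])
    df = pd.DataFrame({"time": t, "id": "p", "x": x, "y": 0.0})
    segs = filter_atypical(df, BOUNDS)
    assert len(segs) == 2
    gap_start = segs[0]["time"].iloc[-1]
    gap_end = segs[1]["time"].iloc[0]
    assert 2.5 < gap_start < 3.5 and 5.5 < gap_end < 6.5


def test_filtering_is_idempotent():
    rng = np.random.default_rng(0)
    df = straight_walker(0, 0, 1.2, 0.0)
    df["x"] += rng.normal(0, 0.01, len(df))
    for seg in filter_atypical(df, BOUNDS):
        again = filter_atypical(seg, BOUNDS)
        assert len(again) == 1
        pd.testing.assert_frame_equal(again[0], seg.reset_index(drop=True))


def test_group_center_is_midpoint():
    m1 = straight_walker(0, 1, 1.2, 0, pid="a")
    m2 = straight_walker(0, -1, 1.2, 0, pid="b")
    gt = build_group_track(m1, m2, "g", "friends")
    assert np.allclose(gt.data[["cx", "cy"]].iloc[0], [0, 0])
    assert np.allclose(gt.data["sep"], 2.0)


def test_group_center_translation_equivariance():
    m1 = straight_walker(0, 1, 1.2, 0, pid="a")
    m2 = straight_walker(0, -1, 1.2, 0, pid="b")
    base = build_group_track(m1, m2, "g", "friends")
    shifted = build_group_track(
        m1.assign(x=m1.x + 5, y=m1.y + 5),
        m2.assign(x=m2.x + 5, y=m2.y + 5), "g", "friends")
    assert np.allclose(shifted.data["cx"], base.data["cx"] + 5)
    assert np.allclose(shifted.data["cy"], base.data["cy"] + 5)
    assert np.allclose(shifted.data["sep"], base.data["sep"])


def test_group_track_empty_overlap_skips():
    m1 = straight_walker(0, 1, 1.2, 0, t0=0, t1=2, pid="a")
    m2 = straight_walker(0, -1, 1.2, 0, t0=5, t1=7, pid="b")
    with pytest.raises(SkipEncounter):
        build_group_track(m1, m2, "g", "friends")


def test_class_distance_unweighted_mean():
    def track(sep, gid):
        m1 = straight_walker(0, sep / 2, 1.2, 0, pid="a")
        m2 = straight_walker(0, -sep / 2, 1.2, 0, pid="b")
        return build_group_track(m1, m2, gid, "friends")
    tracks = [track(0.6, "g1"), track(1.0, "g2")]
    assert class_interpersonal_distance(tracks, "friends") == pytest.approx(0.8)
    with pytest.raises(ValidationError, match="couples"):
        class_interpersonal_distance(tracks, "couples")


def _simple_group(vx=0.0, vy=1.0, x0=5.0, y0=5.0):
    m1 = straight_walker(x0 - 0.3, y0, vx, vy, pid="a")
    m2 = straight_walker(x0 + 0.3, y0, vx, vy, pid="b")
    return build_group_track(m1, m2, "g", "friends")


def test_frame_transform_quarter_turn():
    """Group at (5,5) moving +y, individual at (5,6): the group frame puts
    the individual at (1, 0) — ahead of the group along its heading."""
    gt = _simple_group()
    ind = with_velocities(straight_walker(5, 6, 0, 1.0, pid="i"))
    frame = to_group_frame(gt, ind)
    assert np.allclose(frame.pos[0], [1.0, 0.0], atol=1e-9)


def test_frame_preserves_relative_norms():
    rng = np.random.default_rng(3)
    gt = _simple_group(vx=0.7, vy=0.9)
    ind = straight_walker(6, 3, -0.6, 0.8, pid="i")
    ind["x"] += rng.normal(0, 0.01, len(ind))
    ind["y"] += rng.normal(0, 0.01, len(ind))
    frame = to_group_frame(gt, ind)
    assert np.allclose(np.hypot(*frame.pos.T), np.hypot(*frame.pos_rel.T),
                       rtol=1e-9)
    assert np.allclose(np.hypot(*frame.vel.T), np.hypot(*frame.vel_rel.T),
                       rtol=1e-9)


def test_stationary_group_skips():
    m1 = straight_walker(-0.3, 0, 0, 0, pid="a")
    m2 = straight_walker(0.3, 0, 0, 0, pid="b")
    gt = build_group_track(m1, m2, "g", "friends")
    ind = straight_walker(6, 0, -1.2, 0, pid="i")
    with pytest.raises(SkipEncounter):
        to_group_frame(gt, ind)


def test_comoving_individual_excluded(config):
    gt = _simple_group(vx=1.2, vy=0.0, x0=0.0, y0=0.0)
    ind = with_velocities(straight_walker(-2, 1, 1.2, 0, pid="i"))
    assert select_frontal_encounters(gt, ind, "i", config) == []


def test_head_on_included(config):
    gt = _simple_group(vx=1.2, vy=0.0, x0=0.0, y0=0.0)
    ind = with_velocities(straight_walker(10, 0.5, -1.2, 0, pid="i"))
    encs = select_frontal_encounters(gt, ind, "i", config)
    assert len(encs) == 1
    assert encs[0].angle_at_entry == pytest.approx(180.0, abs=1e-6)
    assert not encs[0].begins_inside


def test_simulated_frontal_recall(null_dataset, config):
    """Every generator-intended frontal encounter whose lateral offset fits
    inside the window is recovered."""
    from pedscatter import extract_encounters
    traj, annot, truth = null_dataset
    _, encounters, _ = extract_encounters(config, traj, annot)
    expected = truth[truth["offset"].abs() < config.window_half_width - 0.2]
    found_groups = {e.group_id.split("~")[0] for e in encounters}
    missing = [f"{e}_g" for e in expected["encounter_id"]
               if f"{e}_g" not in found_groups]
    assert missing == []
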