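import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedscatter import (anova_per_bin, bin_pairs, density_map, intrusion_table,
                        rb_linear_correction)
from pedscatter.exceptions import ValidationError


def obs_frame(rb, r0, label="c"):
    rb = np.asarray(rb, float)
    labels = [label] * len(rb) if isinstance(label, str) else label
    return pd.DataFrame({"class_label": labels, "rbar_b": rb, "rbar_0": r0})


def test_bin_means_and_half_open_edges():
    df = obs_frame([0.2, 0.4, 0.5], [1.0, 2.0, 7.0])
    out = bin_pairs(df, 0.5)
    b0 = out[(out.bin_lo == 0.0)].iloc[0]
    assert b0["n"] == 2 and b0["mean_r0"] == pytest.approx(1.5)
    b1 = out[(out.bin_lo == 0.5)].iloc[0]
    assert b1["n"] == 1 and b1["mean_r0"] == 7.0  # 0.5 goes to [0.5, 1)


def test_bins_cover_all_encounters():
    rng = np.random.default_rng(5)
    rb = rng.uniform(0, 6, 500)
    df = obs_frame(rb, rb + rng.normal(0, 0.1, 500),
                   label=list(rng.choice(["a", "b"], 500)))
    out = bin_pairs(df, 0.5)
    assert out["n"].sum() == 500


def test_null_binned_means_track_bin_mean():
    """With r0 = rb exactly, the per-bin mean minimum distance equals the
    per-bin mean straight-line distance."""
    rng = np.random.default_rng(6)
    rb = rng.uniform(0, 5, 2000)
    out = bin_pairs(obs_frame(rb, rb), 0.5)
    filled = out[out.n > 0]
    assert np.allclose(filled["mean_r0"], filled["mean_rb"], atol=1e-12)


def test_anova_identical_samples_p_one():
    df = obs_frame([0.1] * 8, [1.0] * 8, label=["a"] * 4 + ["b"] * 4)
    out = anova_per_bin(df, 0.5)
    assert out.iloc[0]["F"] == 0.0 and out.iloc[0]["p"] == 1.0


def test_anova_separated_means_significant():
    rng = np.random.default_rng(2)
    r0 = np.concatenate([rng.normal(1, 0.1, 50), rng.normal(5, 0.1, 50)])
    df = obs_frame([0.2] * 100, r0, label=["a"] * 50 + ["b"] * 50)
    out = anova_per_bin(df, 0.5)
    assert out.iloc[0]["p"] < 1e-6
    # agrees with an independently computed F statistic
    F_ref, p_ref = stats.f_oneway(r0[:50], r0[50:])
    assert out.iloc[0]["F"] == pytest.approx(F_ref)
    assert out.iloc[0]["p"] == pytest.approx(p_ref)


def test_anova_single_class_missing_with_reason():
    df = obs_frame([0.1, 0.2, 0.3], [1, 2, 3])
    out = anova_per_bin(df, 0.5)
    assert np.isnan(out.iloc[0]["p"]) and out.iloc[0]["reason"] == "single class"


def test_intrusion_probability_simple():
    df = obs_frame([0.1, 0.2, 0.3, 0.4], [0.4, 0.8, 1.2, 1.6])
    out = intrusion_table(df, thresholds=(1.0,), bin_width=0.5)
    assert out.iloc[0]["probability"] == 0.5


def test_intrusion_monotone_in_threshold():
    rng = np.random.default_rng(8)
    df = obs_frame(rng.uniform(0, 1, 200), rng.uniform(0, 2, 200))
    t1 = intrusion_table(df, thresholds=(1.0,), bin_width=10.0)
    t05 = intrusion_table(df, thresholds=(0.5,), bin_width=10.0)
    assert (t05["probability"] <= t1["probability"] + 1e-12).all()


def test_chi2_identical_counts_p_one():
    df = obs_frame([0.1] * 20, [0.5] * 5 + [1.5] * 5 + [0.5] * 5 + [1.5] * 5,
                   label=["a"] * 10 + ["b"] * 10)
    out = intrusion_table(df, thresholds=(1.0,), bin_width=0.5)
    assert np.allclose(out["p"], 1.0)


def test_chi2_matches_hand_computation():
    """Pearson chi-squared on [[10, 90], [40, 60]] equals the textbook
    sum((O - E)^2 / E) with expected counts from the margins."""
    r0 = np.concatenate([np.full(10, 0.5), np.full(90, 1.5),
                         np.full(40, 0.5), np.full(60, 1.5)])
    df = obs_frame([0.1] * 200, r0, label=["a"] * 100 + ["b"] * 100)
    out = intrusion_table(df, thresholds=(1.0,), bin_width=0.5)
    O = np.array([[10, 90], [40, 60]])
    E = np.outer(O.sum(1), O.sum(0)) / O.sum()
    chi2_hand = ((O - E) ** 2 / E).sum()
    assert out.iloc[0]["chi2"] == pytest.approx(chi2_hand)
    assert out.iloc[0]["p"] == pytest.approx(stats.chi2.sf(chi2_hand, 1))


def test_rb_correction_identity_on_unbiased_data():
    rng = np.random.default_rng(3)
    rb = rng.uniform(0, 6, 300)
    out, corr = rb_linear_correction(obs_frame(rb, rb), floor=2.0)
    assert corr.applied
    assert corr.slope == pytest.approx(1.0, abs=1e-9)
    assert corr.intercept == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(out["rbar_b"], rb, atol=1e-9)


def test_rb_correction_removes_constructed_bias():
    rng = np.random.default_rng(4)
    rb = rng.uniform(0, 6, 300)
    out, corr = rb_linear_correction(obs_frame(rb, 0.9 * rb), floor=2.0)
    assert corr.slope == pytest.approx(0.9, abs=1e-9)
    assert np.allclose(out["rbar_b"], 0.9 * rb, atol=1e-9)


def test_rb_correction_skipped_with_few_points():
    out, corr = rb_linear_correction(obs_frame([0.1, 0.2], [0.1, 0.2]),
                                     floor=2.0)
    assert not corr.applied and corr.slope == 1.0


def test_density_single_point():
    m = density_map(np.array([[0.05, 0.05]]), (-1, 1, -1, 1), cell=0.1)
    assert m.values.max() == 1.0
    assert (m.values == 1.0).sum() == 1
    assert m.values.sum() == 1.0


def test_density_empty_raises():
    with pytest.raises(ValidationError):
        density_map(np.empty((0, 2)), (-1, 1, -1, 1))


def test_relative_maps_sum_to_zero():
    rng = np.random.default_rng(9)
    pts = rng.uniform(-2, 2, (600, 2))
    labels = rng.choice(["a", "b", "c"], 600)
    maps = density_map(pts, (-2, 2, -2, 2), cell=0.25, mode="relative",
                       class_labels=labels)
    total = sum(m.values for m in maps.values())
    assert np.abs(total).max() < 1e-12


def test_out_of_extent_points_counted():
    pts = np.array([[0.0, 0.0], [5.0, 5.0]])
    m = density_map(pts, (-1, 1, -1, 1), cell=0.5)
    assert m.n_dropped == 1
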