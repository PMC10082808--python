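"""Binned statistics, intrusion probabilities and density maps.

The scaled straight-line distance is quantized into fixed-width bins
(default 0.5 interpersonal-distance units, half-open, anchored at zero) and
the mean and standard error of the scaled minimum distance are computed per
(class, bin).  Class differences are tested bin-by-bin with a one-way ANOVA
on the per-encounter minimum distances, and intrusion frequencies (minimum
distance below a threshold) with Pearson's chi-squared test of independence
on the class-by-outcome contingency table.  A linear calibration of the
straight-line distance against the minimum distance in the
large-separation regime compensates environment-induced bias (in a straight
unconstrained corridor it reduces to the identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

log = logging.getLogger(__name__)


def bin_pairs(obs: pd.DataFrame, bin_width: float = 0.5,
              rb_col: str = "rbar_b", r0_col: str = "rbar_0") -> pd.DataFrame:
    """Quantize the straight-line distance and aggregate the minimum
    distance per (class, bin).

    Bins are half-open ``[k*w, (k+1)*w)`` anchored at 0.  Returns one row
    per (class, bin) including empty bins (n=0) up to the largest occupied
    bin, with columns: class_label, bin_lo, bin_hi, bin_mid, n, mean_rb,
    mean_r0, sem_r0 (SEM defined for n >= 2).
    """
    if obs.empty:
        return pd.DataFrame(columns=[
            "class_label", "bin_lo", "bin_hi", "bin_mid", "n",
            "mean_rb", "mean_r0", "sem_r0", "sem_rb", "cov_means"])
    rb = obs[rb_col].to_numpy(float)
    r0 = obs[r0_col].to_numpy(float)
    idx = np.floor(rb / bin_width).astype(int)
    idx = np.maximum(idx, 0)
    n_bins = int(idx.max()) + 1
    rows = []
    for label, sub in obs.assign(_bin=idx, _rb=rb, _r0=r0).groupby(
            "class_label", sort=True):
        for b in range(n_bins):
            sel = sub[sub["_bin"] == b]
            n = len(sel)
            mean_rb = float(sel["_rb"].mean()) if n else np.nan
            mean_r0 = float(sel["_r0"].mean()) if n else np.nan
            sem = float(sel["_r0"].std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            sem_rb = float(sel["_rb"].std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            # covariance of the two bin means (r0 and rb are positively
            # correlated within a bin); used when propagating uncertainty
            # into the potential probe
            cov = (float(np.cov(sel["_r0"], sel["_rb"], ddof=1)[0, 1]) / n
                   if n >= 2 else np.nan)
            rows.append({
                "class_label": label,
                "bin_lo": b * bin_width, "bin_hi": (b + 1) * bin_width,
                "bin_mid": (b + 0.5) * bin_width,
                "n": n, "mean_rb": mean_rb, "mean_r0": mean_r0, "sem_r0": sem,
                "sem_rb": sem_rb, "cov_means": cov,
            })
    return pd.DataFrame(rows)


def anova_per_bin(obs: pd.DataFrame, bin_width: float = 0.5,
                  rb_col: str = "rbar_b", r0_col: str = "rbar_0") -> pd.DataFrame:
    """One-way fixed-effects ANOVA of the minimum distance across classes,
    separately in each straight-line-distance bin.

    Bins with fewer than two classes contributing at least two encounters
    each get a missing p-value with the reason recorded.  When the
    between-class variance is exactly zero the F statistic is 0 and p = 1.
    """
    if obs.empty:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "n", "F", "p", "reason"])
    rb = obs[rb_col].to_numpy(float)
    idx = np.maximum(np.floor(rb / bin_width).astype(int), 0)
    rows = []
    for b in range(int(idx.max()) + 1):
        sel = obs[idx == b]
        groups = [g[r0_col].to_numpy(float)
                  for _, g in sel.groupby("class_label") if len(g) >= 2]
        row = {"bin_lo": b * bin_width, "bin_hi": (b + 1) * bin_width,
               "n": len(sel), "F": np.nan, "p": np.nan, "reason": ""}
        if len(groups) < 2:
            row["reason"] = ("single class" if len(groups) == 1 else
                             "insufficient data")
        else:
            grand = np.mean(np.concatenate(groups))
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            if ssb == 0.0:
                row["F"], row["p"] = 0.0, 1.0
            else:
                F, p = stats.f_oneway(*groups)
                row["F"], row["p"] = float(F), float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def intrusion_table(obs: pd.DataFrame, thresholds: tuple[float, ...] = (1.0, 0.5),
                    bin_width: float = 0.5, rb_col: str = "rbar_b",
                    r0_col: str = "rbar_0") -> pd.DataFrame:
    """Per-(class, bin) intrusion probabilities with per-bin chi-squared
    tests.

    For each threshold the intrusion probability is the fraction of
    encounters in the (class, bin) cell with minimum distance below the
    threshold.  Per bin and threshold, Pearson's chi-squared test (no
    continuity correction) assesses independence of intrusion frequency and
    class on the class x {intrude, pass} table; the p-value is flagged
    unreliable when any expected count falls below 1, and degenerate tables
    (an all-zero outcome column) yield p = 1.
    """
    if obs.empty:
        return pd.DataFrame(columns=[
            "threshold", "bin_lo", "bin_hi", "class_label", "n",
            "n_intrusions", "probability", "chi2", "p", "flag"])
    rb = obs[rb_col].to_numpy(float)
    r0 = obs[r0_col].to_numpy(float)
    idx = np.maximum(np.floor(rb / bin_width).astype(int), 0)
    rows = []
    for thr in thresholds:
        intr = r0 < thr
        for b in range(int(idx.max()) + 1):
            in_bin = idx == b
            sub = obs[in_bin]
            counts = []
            labels = sorted(sub["class_label"].unique())
            for label in labels:
                m = in_bin & (obs["class_label"] == label).to_numpy()
                n = int(m.sum())
                k = int((intr & m).sum())
                counts.append((label, n, k))
            table = np.array([[k, n - k] for _, n, k in counts if n > 0])
            chi2 = p = np.nan
            flag = ""
            if len(table) >= 2:
                col_sums = table.sum(axis=0)
                if (col_sums == 0).any():
                    chi2, p, flag = 0.0, 1.0, "degenerate"
                else:
                    res = stats.chi2_contingency(table, correction=False)
                    chi2, p = float(res[0]), float(res[1])
                    if (res[3] < 1).any():
                        flag = "low_expected_counts"
            else:
                flag = "single_class" if len(table) == 1 else "empty"
            for label, n, k in counts:
                rows.append({
                    "threshold": thr,
                    "bin_lo": b * bin_width, "bin_hi": (b + 1) * bin_width,
                    "class_label": label, "n": n, "n_intrusions": k,
                    "probability": k / n if n else np.nan,
                    "chi2": chi2, "p": p, "flag": flag,
                })
    return pd.DataFrame(rows)


@dataclass
class LinearCorrection:
    slope: float
    intercept: float
    n_calibration: int
    applied: bool

    def __call__(self, rb: np.ndarray) -> np.ndarray:
        if not self.applied:
            return np.asarray(rb, float)
        return self.slope * np.asarray(rb, float) + self.intercept


def rb_linear_correction(obs: pd.DataFrame, floor: float = 2.0,
                         min_points: int = 10, rb_col: str = "rbar_b",
                         r0_col: str = "rbar_0") -> tuple[pd.DataFrame, LinearCorrection]:
    """Calibrate the straight-line distance against the minimum distance.

    In the regime ``rbar_b >= floor`` collision avoidance is negligible and
    the two observables should coincide; a least-squares line
    ``rbar_0 = a * rbar_b + c`` fitted there captures any environment bias,
    and the corrected value ``a * rbar_b + c`` is applied to all encounters
    (columns ``<rb_col>_raw`` preserved).  With too few calibration points
    the identity is used and a warning logged.
    """
    rb = obs[rb_col].to_numpy(float)
    r0 = obs[r0_col].to_numpy(float)
    sel = rb >= floor
    if sel.sum() < min_points:
        log.warning("rb linear correction skipped: %d calibration points "
                    "(need %d)", int(sel.sum()), min_points)
        corr = LinearCorrection(1.0, 0.0, int(sel.sum()), applied=False)
        return obs.copy(), corr
    a, c = np.polyfit(rb[sel], r0[sel], 1)
    corr = LinearCorrection(float(a), float(c), int(sel.sum()), applied=True)
    out = obs.copy()
    out[rb_col + "_raw"] = rb
    out[rb_col] = corr(rb)
    log.info("rb linear correction: slope=%.4f intercept=%.4f (n=%d)",
             a, c, int(sel.sum()))
    return out, corr


@dataclass
class DensityMap:
    """2D occupancy histogram of relative positions.

    ``values[iy, ix]`` covers the cell with lower corner
    ``(origin[0] + ix*cell, origin[1] + iy*cell)``.  ``mode`` is
    ``"cumulative-normalized"`` (histogram scaled by its maximum, max = 1)
    or ``"relative"`` (per-class probability map minus the unweighted
    cross-class mean; cells may be negative).
    """

    origin: tuple[float, float]
    cell: float
    values: np.ndarray
    mode: str
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.values.shape
        return pd.DataFrame(
            self.values,
            index=[self.origin[1] + self.cell * iy for iy in range(ny)],
            columns=[self.origin[0] + self.cell * ix for ix in range(nx)],
        )

    def plot(self, path, title: str = "") -> None:
        """Render the map to an image file (PNG etc.)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ny, nx = self.values.shape
        extent = (self.origin[0], self.origin[0] + nx * self.cell,
                  self.origin[1], self.origin[1] + ny * self.cell)
        fig, ax = plt.subplots(figsize=(5, 4))
        cmap = "coolwarm" if self.mode == "relative" else "viridis"
        vmax = np.abs(self.values).max() or 1.0
        vmin = -vmax if self.mode == "relative" else 0.0
        im = ax.imshow(self.values, origin="lower", extent=extent,
                       cmap=cmap, vmin=vmin, vmax=vmax, aspect="equal")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _histogram(x: np.ndarray, y: np.ndarray, extent: tuple[float, float, float, float],
               cell: float) -> tuple[np.ndarray, int]:
    x0, x1, y0, y1 = extent
    nx = max(1, int(np.ceil((x1 - x0) / cell)))
    ny = max(1, int(np.ceil((y1 - y0) / cell)))
    keep = (x >= x0) & (x < x0 + nx * cell) & (y >= y0) & (y < y0 + ny * cell)
    H, _, _ = np.histogram2d(
        y[keep], x[keep],
        bins=[ny, nx],
        range=[[y0, y0 + ny * cell], [x0, x0 + nx * cell]],
    )
    return H, int((~keep).sum())


def density_map(positions: np.ndarray, extent: tuple[float, float, float, float],
                cell: float = 0.10, mode: str = "cumulative-normalized",
                class_labels: np.ndarray | None = None
                ) -> DensityMap | dict[str, DensityMap]:
    """Build occupancy maps of relative positions on a fixed grid.

    ``positions`` is (n, 2); points outside ``extent`` are dropped and
    counted.  In ``"cumulative-normalized"`` mode a single map scaled by its
    maximum is returned.  In ``"relative"`` mode ``class_labels`` (length n)
    is required and a dict label -> map is returned where each class map is
    probability-normalized and the unweighted mean over classes is
    subtracted, so the class maps sum to zero cell-wise.
    """
    positions = np.asarray(positions, float)
    if positions.size == 0:
        raise ValidationError("density_map: empty input")
    x, y = positions[:, 0], positions[:, 1]
    x0 = extent[0]
    y0 = extent[2]
    if mode == "cumulative-normalized":
        H, dropped = _histogram(x, y, extent, cell)
        peak = H.max()
        if peak > 0:
            H = H / peak
        return DensityMap((x0, y0), cell, H, mode, dropped)
    if mode == "relative":
        if class_labels is None:
            raise ValidationError("relative maps need class labels")
        class_labels = np.asarray(class_labels)
        maps = {}
        dropped = {}
        for label in sorted(np.unique(class_labels)):
            sel = class_labels == label
            H, nd = _histogram(x[sel], y[sel], extent, cell)
            total = H.sum()
            maps[label] = H / total if total > 0 else H
            dropped[label] = nd
        mean = np.mean(list(maps.values()), axis=0)
        return {
            label: DensityMap((x0, y0), cell, maps[label] - mean, mode,
                              dropped[label])
            for label in maps
        }
    raise ValidationError(f"unknown density map mode {mode!r}")
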