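"""Leaf-count to plant-count regression with leave-one-out cross-validation.

The number of unfolded leaves per rapeseed plant is tied to its growth
stage, so at a fixed observation date the plot-level plant count y is
approximately linear in the plot-level leaf count x:  y = a*x + b, with the
slope a close to the inverse of the mean leaves-per-plant at that stage
(about 1/3 at the one- to three-leaf stage, 1/5 at the four- to six-leaf
stage).

With only a handful of training plots per date, the model is fitted by
LOOCV: each fold leaves one plot out, fits a simple linear regression on
the rest and predicts the held-out plot; the final coefficients are the
arithmetic mean of the per-fold coefficients (not a refit on all data), and
RMSE / MAE / R^2 are computed from the held-out predictions only:

    RMSE  = sqrt( sum (y_i - yhat_i)^2 / n )
    MAE   = sum |y_i - yhat_i| / n
    R^2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

Applying a fitted model to the CNN's overcounting-calibrated leaf count of
a test plot yields its stand-count estimate; plot estimates are rounded
half-away-from-zero for reporting, and summed/averaged estimates are judged
by mean accuracy (100 * estimate / truth), RMSE over plots and relative
RMSE (100 * RMSE / mean per-plot truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import LinearTrend

__all__ = [
    "LeafToPlantModel",
    "LeafToPlantResults",
    "EstimateReport",
    "loocv_fit",
    "estimate_stand_count",
    "round_half_away",
    "evaluate_estimates",
    "summarize_size_totals",
    "relative_rmse",
    "fit_coefficient_vs_dap",
]


def round_half_away(x) -> np.ndarray | int:
    """Round half away from zero (318.54 -> 319, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return int(out) if out.ndim == 0 else out.astype(int)


@dataclass
class LeafToPlantResults:
    """Fitted per-date counting model y = slope*x + intercept with LOOCV
    diagnostics computed on held-out predictions."""

    slope: float
    intercept: float
    r2_loocv: float
    mae: float
    rmse: float
    n_folds: int
    dap: int | None = None
    fold_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold_intercepts: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold_pvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    heldout_predictions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, leaf_count):
        """Unrounded plant-count prediction a*x + b."""
        x = np.asarray(leaf_count, dtype=float)
        out = self.slope * x + self.intercept
        return float(out) if out.ndim == 0 else out

    def estimate(self, leaf_count):
        """Plant-count estimate rounded half-away-from-zero to an integer."""
        return round_half_away(self.predict(leaf_count))

    def summary(self) -> str:
        dap = f"{self.dap} DAP" if self.dap is not None else "single date"
        lines = [
            "Leaf-to-plant counting model (LOOCV)",
            "=" * 44,
            f"Observation:        {dap}",
            f"Folds (plots):      {self.n_folds}",
            f"Formula:            y = {self.slope:.3f} x + {self.intercept:.3f}",
            f"R^2 (LOOCV):        {self.r2_loocv:.3f}",
            f"MAE  (held-out):    {self.mae:.1f} plants",
            f"RMSE (held-out):    {self.rmse:.1f} plants",
        ]
        if self.fold_pvalues.size:
            lines.append(
                f"Fold slope p-vals:  min {self.fold_pvalues.min():.3g}, "
                f"max {self.fold_pvalues.max():.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dap": self.dap,
            "a": self.slope,
            "b": self.intercept,
            "r2_loocv": self.r2_loocv,
            "mae": self.mae,
            "rmse": self.rmse,
            "n_folds": self.n_folds,
        }


class LeafToPlantModel:
    """Per-observation linear model of plant count against leaf count.

    Parameters
    ----------
    leaf_counts : array-like
        Plot-level leaf counts x (ground-truth outlines for training).
    plant_counts : array-like
        Plot-level plant counts y (ground truth).
    dap : int, optional
        Observation date tag carried through to the results.
    """

    def __init__(self, leaf_counts, plant_counts, dap: int | None = None):
        self.x = np.asarray(leaf_counts, dtype=float)
        self.y = np.asarray(plant_counts, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("leaf_counts and plant_counts must be equal-length 1-D")
        if self.x.size < 3:
            raise ValueError("need at least 3 plots for LOOCV fitting")
        self.dap = dap

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        x_col: str = "leaf_count",
        y_col: str = "plant_count",
        dap: int | None = None,
    ) -> "LeafToPlantModel":
        return cls(data[x_col].to_numpy(), data[y_col].to_numpy(), dap=dap)

    def fit(self) -> LeafToPlantResults:
        n = self.x.size
        slopes = np.empty(n)
        intercepts = np.empty(n)
        pvalues = np.empty(n)
        preds = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            xt, yt = self.x[keep], self.y[keep]
            if np.ptp(xt) == 0:
                raise ValueError(f"fold {i}: zero variance in leaf counts")
            res = stats.linregress(xt, yt)
            slopes[i] = res.slope
            intercepts[i] = res.intercept
            pvalues[i] = res.pvalue
            preds[i] = res.slope * self.x[i] + res.intercept

        resid = self.y - preds
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
        return LeafToPlantResults(
            slope=float(slopes.mean()),
            intercept=float(intercepts.mean()),
            r2_loocv=r2,
            mae=float(np.abs(resid).mean()),
            rmse=float(np.sqrt((resid**2).mean())),
            n_folds=n,
            dap=self.dap,
            fold_slopes=slopes,
            fold_intercepts=intercepts,
            fold_pvalues=pvalues,
            heldout_predictions=preds,
        )


def loocv_fit(pairs, dap: int | None = None) -> LeafToPlantResults:
    """Fit a counting model from (leaf_count, plant_count) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return LeafToPlantModel(arr[:, 0], arr[:, 1], dap=dap).fit()


def estimate_stand_count(model: LeafToPlantResults, leaf_count) -> int:
    """Rounded plant-count estimate for a given leaf count."""
    if np.any(np.asarray(leaf_count) < 0):
        raise ValueError("leaf_count must be >= 0")
    return model.estimate(leaf_count)


# -- estimate evaluation -----------------------------------------------------


@dataclass
class EstimateReport:
    """Per-plot and aggregate stand-count estimates with accuracy metrics.

    ``per_plot`` columns: plot_id, dap, patch_size, leaf_count_used,
    estimate, truth. ``totals`` holds one row per (dap, patch_size) with the
    summed test-plot estimate and truth plus RMSE/rRMSE over plots;
    ``by_dap`` averages the per-size totals per date: the mean estimate
    (unrounded mean of the per-size sums), mean accuracy
    100 * mean_estimate / truth, mean RMSE and mean rRMSE.
    """

    per_plot: pd.DataFrame
    totals: pd.DataFrame
    by_dap: pd.DataFrame

    def summary(self) -> str:
        lines = ["Stand-count estimation report", "=" * 44]
        for _, row in self.by_dap.iterrows():
            lines.append(
                f"{int(row['dap']):>3} DAP: mean estimate "
                f"{round_half_away(row['mean_estimate']):>4d} / "
                f"{int(row['truth'])} plants, mean accuracy "
                f"{row['mean_accuracy']:.2f}%, mean RMSE {row['mean_rmse']:.1f}, "
                f"mean rRMSE {row['mean_rrmse']:.2f}%"
            )
        return "\n".join(lines)


def evaluate_estimates(per_plot: pd.DataFrame) -> EstimateReport:
    """Aggregate per-plot estimates into per-size totals and per-date means.

    ``per_plot`` must have columns plot_id, dap, patch_size,
    leaf_count_used, estimate, truth; estimates and truths are per test
    plot. Plot sets must match across patch sizes within a date.
    """
    required = {"plot_id", "dap", "patch_size", "estimate", "truth"}
    missing = required - set(per_plot.columns)
    if missing:
        raise ValueError(f"per_plot is missing columns: {sorted(missing)}")

    totals_rows = []
    for (dap, size), grp in per_plot.groupby(["dap", "patch_size"]):
        est = grp["estimate"].to_numpy(dtype=float)
        tru = grp["truth"].to_numpy(dtype=float)
        rmse = float(np.sqrt(((est - tru) ** 2).mean()))
        totals_rows.append(
            {
                "dap": dap,
                "patch_size": size,
                "total_estimate": est.sum(),
                "truth": tru.sum(),
                "n_plots": len(grp),
                "rmse": rmse,
                "rrmse": relative_rmse(rmse, tru),
            }
        )
    totals = pd.DataFrame(totals_rows)

    # plot sets must agree across sizes within each date
    for dap, grp in per_plot.groupby("dap"):
        plot_sets = {
            size: frozenset(g["plot_id"]) for size, g in grp.groupby("patch_size")
        }
        if len(set(plot_sets.values())) > 1:
            raise ValueError(f"mismatched test-plot sets across patch sizes at {dap} DAP")

    by_dap_rows = []
    for dap, grp in totals.groupby("dap"):
        mean_est = float(grp["total_estimate"].mean())
        truth = float(grp["truth"].iloc[0])
        if not np.allclose(grp["truth"], truth):
            raise ValueError(f"inconsistent ground truth across sizes at {dap} DAP")
        by_dap_rows.append(
            {
                "dap": dap,
                "mean_estimate": mean_est,
                "truth": truth,
                "mean_accuracy": 100.0 * mean_est / truth,
                "mean_rmse": float(grp["rmse"].mean()),
                "mean_rrmse": float(grp["rrmse"].mean()),
            }
        )
    return EstimateReport(
        per_plot=per_plot.copy(), totals=totals, by_dap=pd.DataFrame(by_dap_rows)
    )


def summarize_size_totals(size_totals, truth: float) -> dict:
    """Average per-patch-size total estimates for one date.

    Returns the unrounded mean, the rounded mean as reported in tables, and
    the mean accuracy 100 * mean / truth computed from the unrounded mean.
    """
    vals = np.asarray(list(size_totals), dtype=float)
    mean = float(vals.mean())
    return {
        "mean_estimate": mean,
        "mean_estimate_rounded": round_half_away(mean),
        "mean_accuracy": 100.0 * mean / truth,
    }


def relative_rmse(rmse: float, per_plot_truths) -> float:
    """rRMSE in percent: 100 * RMSE / mean per-plot ground-truth count."""
    ybar = float(np.mean(np.asarray(per_plot_truths, dtype=float)))
    return 100.0 * rmse / ybar


def fit_coefficient_vs_dap(models) -> LinearTrend:
    """OLS of the counting-model slope on DAP (diagnostic).

    The slope tracks the inverse of leaves-per-plant, so it declines as
    plants unfold more leaves.
    """
    pts = [(m.dap, m.slope) for m in models]
    if len(pts) < 2:
        raise ValueError("need at least 2 models")
    arr = np.asarray(pts, dtype=float)
    if np.unique(arr[:, 0]).size < 2:
        raise ValueError("models must span at least 2 DAP values")
    if np.ptp(arr[:, 1]) == 0:
        return LinearTrend(
            slope=0.0,
            intercept=float(arr[0, 1]),
            r_squared=0.0,
            n_obs=arr.shape[0],
            y_name="coefficient",
        )
    fit = stats.linregress(arr[:, 0], arr[:, 1])
    return LinearTrend(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_obs=arr.shape[0],
        y_name="coefficient",
    )
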