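"""Overcounting-calibrated detection statistics.

Detected leaf points are matched to ground-truth leaf outline masks by
point-in-polygon containment. With N detected points, M masks and C_i the
number of points inside mask i, the bookkeeping is a partition of the
detections:

    N  = TP + FP + sum_i (C_i - 1)   over masks with C_i > 1
    M  = TP + FN
    R_oc = sum_i (C_i - 1) / N       (overcounting rate)

A mask holding at least one point is a true positive (a detected leaf);
surplus points inside an already-detected mask are overcounts — typical
when a large leaf produces several heat-map maxima — and are removed by
calibration rather than counted as false positives. Calibrated scores:

    precision = TP / ((1 - R_oc) * N)
    recall    = TP / M
    F = 2 * precision * recall / (precision + recall)

Uncalibrated precision TP / (TP + FP) ignores the surplus points entirely
and therefore overstates performance whenever overcounting occurs.

The calibrated leaf count (1 - R_oc) * N = TP + FP is the quantity fed to
the stand-count regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

__all__ = [
    "MatchResult",
    "LinearTrend",
    "match",
    "overcounting_rate",
    "calibrated_scores",
    "calibrated_count",
    "select_best_threshold",
    "fit_roc_vs_dap",
]


@dataclass
class MatchResult:
    """TP/FP/FN/C_i accounting of detections against leaf masks."""

    n_detections: int  # N
    n_masks: int  # M
    tp: int
    fp: int
    fn: int
    per_mask_counts: np.ndarray  # C_i, length M
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.per_mask_counts = np.asarray(self.per_mask_counts, dtype=int)
        overcount = int(np.maximum(self.per_mask_counts - 1, 0).sum())
        if self.n_detections != self.tp + self.fp + overcount:
            raise ValueError("detection partition identity violated")
        if self.n_masks != self.tp + self.fn:
            raise ValueError("mask partition identity violated")

    @property
    def overcount(self) -> int:
        """Total surplus points inside already-detected masks."""
        return int(np.maximum(self.per_mask_counts - 1, 0).sum())

    @property
    def r_oc(self) -> float:
        return overcounting_rate(self)

    @property
    def r_oc_percent(self) -> float:
        return 100.0 * overcounting_rate(self)

    @property
    def precision(self) -> float:
        return calibrated_scores(self)[0]

    @property
    def recall(self) -> float:
        return calibrated_scores(self)[1]

    @property
    def f_score(self) -> float:
        return calibrated_scores(self)[2]

    @property
    def uncalibrated_tp(self) -> int:
        """Every point inside a mask counted as a true detection (surplus
        points on an already-detected leaf included)."""
        return int(self.per_mask_counts.sum())

    @property
    def uncalibrated_precision(self) -> float:
        denom = self.uncalibrated_tp + self.fp
        return self.uncalibrated_tp / denom if denom else 0.0

    @property
    def uncalibrated_recall(self) -> float:
        denom = self.uncalibrated_tp + self.fn
        return self.uncalibrated_tp / denom if denom else 0.0

    @property
    def uncalibrated_f_score(self) -> float:
        """F without overcounting calibration; inflated (never below the
        calibrated F) whenever surplus points exist."""
        p, r = self.uncalibrated_precision, self.uncalibrated_recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _as_shapely(mask) -> Polygon:
    if isinstance(mask, Polygon):
        poly = mask
    else:
        verts = getattr(mask, "vertices", mask)
        verts = np.asarray(verts, dtype=float)
        poly = Polygon(zip(verts[:, 1], verts[:, 0]))  # (x, y) = (col, row)
    if not poly.is_valid:
        raise ValueError("invalid mask polygon geometry")
    return poly


def match(dets, masks, threshold: float | None = None) -> MatchResult:
    """Assign detected points to leaf masks and count TP/FP/FN/C_i.

    Each point is assigned to at most one containing mask (boundary counts
    as inside); if several overlapping masks contain it, the mask whose
    centroid is nearest wins, so the detection partition stays exact.
    """
    points = dets.points if hasattr(dets, "points") else np.asarray(dets)
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        points = points.reshape(0, 3)
    thr = threshold if threshold is not None else getattr(dets, "threshold", None)

    polys = [_as_shapely(m) for m in masks]
    centroids = [p.centroid for p in polys]
    m = len(polys)
    counts = np.zeros(m, dtype=int)
    fp = 0
    tree = STRtree(polys) if m else None

    for row in points:
        pt = Point(row[1], row[0])
        hits = []
        if tree is not None:
            for idx in tree.query(pt):
                if polys[idx].covers(pt):
                    hits.append(int(idx))
        if not hits:
            fp += 1
        elif len(hits) == 1:
            counts[hits[0]] += 1
        else:
            d = [pt.distance(centroids[i]) for i in hits]
            counts[hits[int(np.argmin(d))]] += 1

    tp = int((counts > 0).sum())
    return MatchResult(
        n_detections=points.shape[0],
        n_masks=m,
        tp=tp,
        fp=fp,
        fn=m - tp,
        per_mask_counts=counts,
        threshold=thr,
    )


def overcounting_rate(result: MatchResult) -> float:
    """R_oc = sum over masks with C_i > 1 of (C_i - 1), divided by N.

    Stored as a fraction; report as percent via ``r_oc_percent``. Undefined
    (raises) when there are no detections.
    """
    if result.n_detections == 0:
        raise ValueError("overcounting rate is undefined when N = 0")
    return result.overcount / result.n_detections


def calibrated_scores(result: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F-score) with overcounting calibration."""
    if result.n_detections == 0 or result.n_masks == 0:
        raise ValueError("scores require N > 0 and M > 0")
    calibrated_total = (1.0 - overcounting_rate(result)) * result.n_detections
    precision = result.tp / calibrated_total if calibrated_total > 0 else 0.0
    recall = result.tp / result.n_masks
    if precision + recall == 0.0:
        return precision, recall, 0.0
    f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f


def calibrated_count(result: MatchResult) -> int:
    """Overcounting-calibrated leaf count: N minus the surplus points.

    Equals TP + FP, i.e. the rounded value of (1 - R_oc) * N.
    """
    return result.n_detections - result.overcount


def select_best_threshold(
    sweep: list[tuple[float, MatchResult]]
) -> tuple[float, MatchResult]:
    """Smallest threshold attaining the maximum calibrated F-score.

    Thresholds whose match has no detections score F = 0.
    """
    if not sweep:
        raise ValueError("empty sweep")
    best_t, best_res, best_f = None, None, -1.0
    for t, res in sorted(sweep, key=lambda tr: tr[0]):
        f = res.f_score if res.n_detections > 0 and res.n_masks > 0 else 0.0
        if f > best_f:
            best_t, best_res, best_f = t, res, f
    return best_t, best_res


@dataclass
class LinearTrend:
    """OLS fit of a quantity against DAP (or any scalar covariate)."""

    slope: float
    intercept: float
    r_squared: float
    n_obs: int
    x_name: str = "dap"
    y_name: str = "y"

    def predict(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = self.slope * x + self.intercept
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        return (
            f"{self.y_name} = {self.slope:.4f} * {self.x_name} + "
            f"{self.intercept:.4f}  (R^2 = {self.r_squared:.3f}, "
            f"n = {self.n_obs})"
        )


def fit_roc_vs_dap(observations) -> LinearTrend:
    """OLS of overcounting rate (in percent) on days after planting.

    ``observations`` is an iterable of (dap, r_oc_percent) pairs. The rate
    rises with DAP as leaves grow larger than the sampling patch.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.shape[0] < 2 or np.unique(obs[:, 0]).size < 2:
        raise ValueError("need >= 2 observations at distinct DAP values")
    fit = stats.linregress(obs[:, 0], obs[:, 1])
    return LinearTrend(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_obs=obs.shape[0],
        y_name="R_oc(%)",
    )
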