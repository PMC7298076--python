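"""End-to-end experiment orchestration: dates x patch sizes.

One experiment run covers, for every observation date (DAP) and every
sampling patch size: scene generation (or loading), three-class labeling,
patch sampling, CNN training, heat-map inference on the test plots,
dilation local-maximum detection over the threshold grid, overcounting-
calibrated matching, per-date LOOCV counting-model fitting on the training
plots' ground-truth leaf counts, and stand-count estimation on the test
plots from the CNN's calibrated leaf counts. Reports mirror the field
study's table layouts: a per-threshold evaluation table, a counting-model
table, an estimate table with per-size totals, plus trend fits of the
overcounting rate and the model coefficient against DAP.

All randomness flows from the run seed through named SeedSequence children
(one per plot layout, per patch-size training run, per sampling call), so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as cnn_mod
from . import evaluation as ev
from . import regression as reg
from .indices import LEAF, SOIL, WEED, label_pixels
from .localize import default_threshold_grid, threshold_sweep
from .synthetic import PlotScene, SimConfig, generate_observation_series, save_scene

__all__ = [
    "RunConfig",
    "run_experiment",
    "report_patch_footprint",
    "child_seed",
    "learning_rate_grid",
    "sweep_learning_rate",
]


def child_seed(*keys: int) -> int:
    """Deterministic 31-bit child seed derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Experiment-grid configuration.

    The default desk-scale profile (2 m x 1 m plots at 0.25 cm/px, reduced
    patch counts 2000/1000/1000 at the 2:1:1 leaf:weed:soil ratio) runs the
    full pipeline on one CPU in minutes; ``paper_scale()`` restores the
    field geometry (9.5 m x 2 m at 0.18 cm/px) and 20000/10000/10000
    patch counts.
    """

    daps: tuple[int, ...] = (53,)
    patch_sizes: tuple[int, ...] = (16,)
    thresholds: tuple[float, ...] | None = None  # None -> 0.50..1.00 step 0.01
    learning_rate: float = 0.0005
    epochs: int = 25
    batch_size: int = 64
    optimizer: str = "adam"  # desk-scale profile; "sgd" is the classic default
    sample_counts: tuple[int, int, int] = (2000, 1000, 1000)  # leaf, weed, soil
    n_train: int = 6
    n_test: int = 2
    plot_size: tuple[float, float] = (2.0, 1.0)
    resolution: float = 0.25
    rows: int = 4
    row_spacing: float = 20.0
    plants_range: tuple[int, int] = (30, 55)
    weed_density: float = 12.0
    selection: str = "per_plot"  # best-threshold selection: per_plot | pooled
    seed: int = 0
    save_scenes: bool = False

    def __post_init__(self) -> None:
        if not self.patch_sizes:
            raise ValueError("at least one patch size is required")
        if self.n_train < 3 or self.n_test < 1:
            raise ValueError("need >= 3 training and >= 1 test plots")
        if self.selection not in ("per_plot", "pooled"):
            raise ValueError("selection must be 'per_plot' or 'pooled'")

    @classmethod
    def paper_scale(cls, **overrides) -> "RunConfig":
        base = dict(
            daps=(32, 39, 46, 53, 58, 68),
            patch_sizes=(16, 24, 32, 40, 48),
            plot_size=(9.5, 2.0),
            resolution=0.18,
            rows=8,
            row_spacing=20.0,
            plants_range=(380, 480),
            sample_counts=(20000, 10000, 10000),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("daps", "patch_sizes", "sample_counts", "plot_size",
                    "plants_range", "thresholds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def report_patch_footprint(patch_size: int, resolution: float) -> float:
    """Ground footprint of a square patch in cm^2, rounded to 1 decimal.

    E.g. a 48-pixel patch at 0.18 cm/px covers (48*0.18)^2 = 74.6 cm^2.
    """
    if patch_size <= 0 or resolution <= 0:
        raise ValueError("patch_size and resolution must be positive")
    return round((patch_size * resolution) ** 2, 1)


def _make_scenes(config: RunConfig) -> dict[int, list[PlotScene]]:
    """Generate all plots across all dates; returns {dap: [scenes]}."""
    n_plots = config.n_train + config.n_test
    by_dap: dict[int, list[PlotScene]] = {dap: [] for dap in config.daps}
    for i in range(n_plots):
        rng = np.random.default_rng(child_seed(config.seed, 7, i))
        plants = int(rng.integers(config.plants_range[0], config.plants_range[1] + 1))
        sim = SimConfig(
            plot_size=config.plot_size,
            resolution=config.resolution,
            rows=config.rows,
            row_spacing=config.row_spacing,
            plants_per_plot=plants,
            weed_density=config.weed_density,
            seed=child_seed(config.seed, 11, i),
            plot_id=f"plot-{i}",
            role="train" if i < config.n_train else "test",
        )
        for dap, scene in zip(config.daps, generate_observation_series(sim, list(config.daps))):
            by_dap[dap].append(scene)
    return by_dap


def _evaluate_test_plot(heat, scene, thresholds, filter_size: int = 5):
    """Sweep thresholds on one test plot; returns per-threshold MatchResults."""
    sweep = threshold_sweep(heat, thresholds, filter_size=filter_size)
    out = []
    for t, dets in sweep:
        out.append((t, ev.match(dets, scene.leaf_polygons, threshold=t)))
    return out


def _select(sweeps_per_plot: list[list[tuple[float, ev.MatchResult]]], mode: str):
    """Best-threshold choice per test plot (or one pooled threshold)."""
    if mode == "per_plot":
        return [ev.select_best_threshold(s) for s in sweeps_per_plot]
    # pooled: maximize the mean F across plots, then read each plot at it
    thresholds = [t for t, _ in sweeps_per_plot[0]]
    mean_f = []
    for j, t in enumerate(thresholds):
        fs = []
        for s in sweeps_per_plot:
            res = s[j][1]
            fs.append(res.f_score if res.n_detections and res.n_masks else 0.0)
        mean_f.append(np.mean(fs))
    j_best = int(np.argmax(mean_f))  # argmax returns the smallest index on ties
    return [(s[j_best][0], s[j_best][1]) for s in sweeps_per_plot]


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full grid; returns (and optionally writes) the reports.

    The returned dict has keys ``threshold_table``, ``count_models``,
    ``estimates`` (DataFrames / lists) and ``summary`` (JSON-ready). With
    ``out_dir`` set, CSVs and ``summary.json`` are written there.
    """
    thresholds = (
        np.asarray(config.thresholds, dtype=float)
        if config.thresholds is not None
        else default_threshold_grid()
    )
    scenes_by_dap = _make_scenes(config)

    threshold_rows = []
    model_rows = []
    estimate_rows = []
    roc_by_dap = []
    timings = []
    results_by_dap: dict[int, reg.LeafToPlantResults] = {}

    for dap in config.daps:
        scenes = scenes_by_dap[dap]
        train_scenes = [s for s in scenes if s.role == "train"]
        test_scenes = [s for s in scenes if s.role == "test"]

        # Reference counting model from ground-truth leaf outlines.
        pairs = [(len(s.leaf_polygons), s.plant_count) for s in train_scenes]
        count_model = reg.loocv_fit(pairs, dap=dap)
        results_by_dap[dap] = count_model
        model_rows.append(count_model.to_dict())

        train_maps = [label_pixels(s) for s in train_scenes]
        best_roc_pcts = []

        for s_px in config.patch_sizes:
            counts = {
                LEAF: config.sample_counts[0],
                WEED: config.sample_counts[1],
                SOIL: config.sample_counts[2],
            }
            samples = cnn_mod.sample_patches(
                train_scenes, train_maps, s_px, counts,
                seed=child_seed(config.seed, 13, dap, s_px),
            )
            spec = cnn_mod.CnnSpec(
                patch_size=s_px,
                learning_rate=config.learning_rate,
                epochs=config.epochs,
                batch_size=config.batch_size,
                optimizer=config.optimizer,
                seed=child_seed(config.seed, 17, dap, s_px),
            )
            t0 = time.perf_counter()
            model = cnn_mod.train(spec, samples)
            timings.append(
                {"dap": dap, "patch_size": s_px,
                 "train_seconds": time.perf_counter() - t0,
                 "final_loss": model.history[-1]["loss"],
                 "final_accuracy": model.history[-1]["accuracy"]}
            )

            sweeps = []
            for scene in test_scenes:
                heat = cnn_mod.heat_map(model, scene)
                sweep = _evaluate_test_plot(heat, scene, thresholds)
                sweeps.append(sweep)
                for t, res in sweep:
                    row = {
                        "plot_id": scene.plot_id, "dap": dap, "patch_size": s_px,
                        "threshold": t, "N": res.n_detections, "M": res.n_masks,
                        "TP": res.tp, "FP": res.fp, "FN": res.fn,
                    }
                    if res.n_detections and res.n_masks:
                        row.update(
                            R_oc=res.r_oc_percent, precision=res.precision,
                            recall=res.recall, f_score=res.f_score,
                        )
                    else:
                        row.update(R_oc=np.nan, precision=np.nan,
                                   recall=np.nan, f_score=0.0)
                    threshold_rows.append(row)

            chosen = _select(sweeps, config.selection)
            for scene, (t_best, res_best) in zip(test_scenes, chosen):
                leaf_count = ev.calibrated_count(res_best)
                estimate = count_model.estimate(leaf_count)
                r_oc_pct = (
                    res_best.r_oc_percent if res_best.n_detections else np.nan
                )
                best_roc_pcts.append(r_oc_pct)
                estimate_rows.append(
                    {
                        "plot_id": scene.plot_id, "dap": dap, "patch_size": s_px,
                        "best_threshold": t_best,
                        "f_score": res_best.f_score
                        if res_best.n_detections and res_best.n_masks else 0.0,
                        "R_oc": r_oc_pct,
                        "leaf_count_used": leaf_count,
                        "estimate": estimate,
                        "truth": scene.plant_count,
                    }
                )
        roc_by_dap.append((dap, float(np.nanmean(best_roc_pcts))))

    estimates_df = pd.DataFrame(estimate_rows)
    report = reg.evaluate_estimates(estimates_df)

    summary: dict = {
        "config": _config_json(config),
        "count_models": model_rows,
        "estimates": estimate_rows,
        "by_dap": report.by_dap.to_dict(orient="records"),
        "totals": report.totals.to_dict(orient="records"),
        "patch_footprints_cm2": {
            str(s): report_patch_footprint(s, config.resolution)
            for s in config.patch_sizes
        },
        "roc_percent_by_dap": roc_by_dap,
    }
    if len(roc_by_dap) >= 2:
        trend = ev.fit_roc_vs_dap(roc_by_dap)
        summary["roc_vs_dap"] = dataclasses.asdict(trend)
    if len(results_by_dap) >= 2:
        coef_trend = reg.fit_coefficient_vs_dap(list(results_by_dap.values()))
        summary["coefficient_vs_dap"] = dataclasses.asdict(coef_trend)

    out = {
        "threshold_table": pd.DataFrame(threshold_rows),
        "count_models": results_by_dap,
        "estimates": estimates_df,
        "report": report,
        "summary": summary,
        # wall-clock timings are reported separately: they are hardware-
        # dependent and must not enter the deterministic summary
        "timings": timings,
    }

    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        out["threshold_table"].to_csv(out_path / "threshold_eval.csv", index=False)
        pd.DataFrame(model_rows).to_csv(out_path / "count_models.csv", index=False)
        estimates_df.to_csv(out_path / "estimates.csv", index=False)
        report.totals.to_csv(out_path / "totals.csv", index=False)
        report.by_dap.to_csv(out_path / "by_dap.csv", index=False)
        pd.DataFrame(timings).to_csv(out_path / "timings.csv", index=False)
        (out_path / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=_json_default)
        )
        if config.save_scenes:
            for dap, scenes in scenes_by_dap.items():
                for scene in scenes:
                    save_scene(scene, out_path / "scenes")
    return out


def learning_rate_grid() -> tuple[float, ...]:
    """The standard learning-rate experiment grid: 0.0001..0.0014 step 0.0001."""
    return tuple(round(k * 1e-4, 4) for k in range(1, 15))


def sweep_learning_rate(
    config: RunConfig, rates: tuple[float, ...] | None = None
) -> pd.DataFrame:
    """Train and evaluate one grid cell per learning rate.

    Uses the config's first date and first patch size; scenes, labels and
    patch samples are generated once and shared across rates, so only the
    training differs. Returns one row per rate with the final training
    loss/accuracy and the mean best calibrated F-score over the test plots.
    """
    if rates is None:
        rates = learning_rate_grid()
    dap = config.daps[0]
    s_px = config.patch_sizes[0]
    thresholds = (
        np.asarray(config.thresholds, dtype=float)
        if config.thresholds is not None
        else default_threshold_grid()
    )
    scenes = _make_scenes(
        dataclasses.replace(config, daps=(dap,), patch_sizes=(s_px,))
    )[dap]
    train_scenes = [s for s in scenes if s.role == "train"]
    test_scenes = [s for s in scenes if s.role == "test"]
    train_maps = [label_pixels(s) for s in train_scenes]
    counts = {
        LEAF: config.sample_counts[0],
        WEED: config.sample_counts[1],
        SOIL: config.sample_counts[2],
    }
    samples = cnn_mod.sample_patches(
        train_scenes, train_maps, s_px, counts,
        seed=child_seed(config.seed, 13, dap, s_px),
    )
    rows = []
    for lr in rates:
        spec = cnn_mod.CnnSpec(
            patch_size=s_px, learning_rate=lr, epochs=config.epochs,
            batch_size=config.batch_size, optimizer=config.optimizer,
            seed=child_seed(config.seed, 17, dap, s_px),
        )
        model = cnn_mod.train(spec, samples)
        f_best = []
        for scene in test_scenes:
            heat = cnn_mod.heat_map(model, scene)
            sweep = _evaluate_test_plot(heat, scene, thresholds)
            _, res = ev.select_best_threshold(sweep)
            f_best.append(
                res.f_score if res.n_detections and res.n_masks else 0.0
            )
        rows.append(
            {
                "learning_rate": lr,
                "final_loss": model.history[-1]["loss"],
                "final_accuracy": model.history[-1]["accuracy"],
                "mean_best_f_score": float(np.mean(f_best)),
            }
        )
    return pd.DataFrame(rows)


def _config_json(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
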