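"""LOOCV leaf-to-plant regression and estimate evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import standcount as sc
from standcount.regression import LeafToPlantModel, round_half_away

from conftest import small_config


def brute_force_loocv(x, y):
    """Independent enumeration of all leave-one-out folds via polyfit."""
    n = len(x)
    slopes, intercepts, preds = [], [], []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        a, b = np.polyfit(np.asarray(x)[keep], np.asarray(y)[keep], 1)
        slopes.append(a)
        intercepts.append(b)
        preds.append(a * x[i] + b)
    resid = np.asarray(y, dtype=float) - np.asarray(preds)
    return {
        "slope": np.mean(slopes),
        "intercept": np.mean(intercepts),
        "rmse": float(np.sqrt((resid**2).mean())),
        "mae": float(np.abs(resid).mean()),
        "r2": 1 - float((resid**2).sum()) / float(((y - np.mean(y)) ** 2).sum()),
    }


class TestLoocvFit:
    def test_collinear_pairs_recovered_exactly(self):
        x = np.array([10.0, 20, 30, 40, 50, 60])
        res = sc.loocv_fit(list(zip(x, 2 * x + 1)))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.mae == pytest.approx(0.0, abs=1e-9)
        assert res.r2_loocv == pytest.approx(1.0)
        assert res.n_folds == 6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_fold_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 300, size=6)
        y = 0.2 * x + 40 + rng.normal(0, 5, size=6)
        res = sc.loocv_fit(list(zip(x, y)))
        ref = brute_force_loocv(x, y)
        assert res.slope == pytest.approx(ref["slope"])
        assert res.intercept == pytest.approx(ref["intercept"])
        assert res.rmse == pytest.approx(ref["rmse"])
        assert res.mae == pytest.approx(ref["mae"])
        assert res.r2_loocv == pytest.approx(ref["r2"])

    def test_heldout_rmse_exceeds_full_fit_rmse_with_outlier(self):
        x = np.array([10.0, 20, 30, 40, 50, 60])
        y = 2 * x + 1
        y[3] += 40  # one outlier
        res = sc.loocv_fit(list(zip(x, y)))
        full = stats.linregress(x, y)
        full_resid = y - (full.slope * x + full.intercept)
        assert res.rmse > float(np.sqrt((full_resid**2).mean()))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.loocv_fit([(1, 2), (2, 3)])  # too few
        with pytest.raises(ValueError):
            sc.loocv_fit([(5, 1), (5, 2), (5, 3), (5, 4)])  # zero variance

    def test_recovers_inverse_leaves_per_plant_from_generator(self):
        # plots at the four- to six-leaf stage: slope ~ 1/5
        for seed in (0, 1):
            pairs = []
            for i in range(6):
                scene = sc.generate_scene(
                    small_config(100 * seed + i,
                                 plants_per_plot=8 + 2 * i)
                )
                pairs.append((len(scene.leaf_polygons), scene.plant_count))
            res = sc.loocv_fit(pairs, dap=53)
            assert res.slope == pytest.approx(0.2, rel=0.15)

    def test_from_dataframe_and_summary(self):
        df = pd.DataFrame({"leaf_count": [10, 20, 30, 40.0],
                           "plant_count": [3, 5, 7, 9.0]})
        res = LeafToPlantModel.from_dataframe(df, dap=46).fit()
        text = res.summary()
        assert "46 DAP" in text and "y =" in text
        assert res.to_dict()["n_folds"] == 4


class TestEstimate:
    def test_printed_model_coefficients_evaluate_correctly(self):
        m53 = sc.LeafToPlantResults(slope=0.277, intercept=41.540, r2_loocv=0.926,
                                    mae=25, rmse=31, n_folds=6, dap=53)
        assert m53.predict(1000) == pytest.approx(318.54)
        assert sc.estimate_stand_count(m53, 1000) == 319
        m68 = sc.LeafToPlantResults(slope=0.214, intercept=46.388, r2_loocv=0.806,
                                    mae=31, rmse=42, n_folds=6, dap=68)
        assert sc.estimate_stand_count(m68, 0) == 46

    def test_zero_leaves_gives_rounded_intercept(self):
        m = sc.LeafToPlantResults(slope=0.3, intercept=14.6, r2_loocv=1.0,
                                  mae=0, rmse=0, n_folds=6)
        assert sc.estimate_stand_count(m, 0) == 15

    def test_negative_leaf_count_rejected(self):
        m = sc.LeafToPlantResults(slope=0.3, intercept=1.0, r2_loocv=1.0,
                                  mae=0, rmse=0, n_folds=6)
        with pytest.raises(ValueError):
            sc.estimate_stand_count(m, -1)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(318.54) == 319
        assert round_half_away(0.5) == 1
        assert round_half_away(1.5) == 2
        assert round_half_away(-0.5) == -1


class TestEvaluateEstimates:
    @staticmethod
    def table_row(dap, size_totals, truth):
        """Per-plot frame for one date; two test plots split each total."""
        rows = []
        for size, total in size_totals.items():
            for plot, est, tru in (("A", total // 2, truth // 2),
                                   ("B", total - total // 2, truth - truth // 2)):
                rows.append(dict(plot_id=plot, dap=dap, patch_size=size,
                                 leaf_count_used=np.nan, estimate=est, truth=tru))
        return rows

    def test_per_size_totals_average_to_mean_accuracy(self):
        sizes = dict(zip((16, 24, 32, 40, 48), (801, 806, 812, 804, 807)))
        df = pd.DataFrame(self.table_row(53, sizes, 812))
        report = sc.evaluate_estimates(df)
        row = report.by_dap.iloc[0]
        assert row["mean_estimate"] == pytest.approx(806.0)
        assert row["mean_accuracy"] == pytest.approx(99.26, abs=5e-3)
        assert "99.26" in report.summary()

    def test_summarize_size_totals_reproduces_printed_accuracies(self):
        s32 = sc.summarize_size_totals((593, 672, 657, 640, 590), 840)
        assert s32["mean_estimate_rounded"] == 630
        assert s32["mean_accuracy"] == pytest.approx(75.05, abs=5e-3)
        s39 = sc.summarize_size_totals((567, 734, 668, 640, 657), 783)
        assert s39["mean_accuracy"] == pytest.approx(83.42, abs=5e-3)

    def test_relative_rmse_identity(self):
        # RMSE of 9 plants over two plots totalling 812 -> 100*9/406
        assert sc.relative_rmse(9.0, [406, 406]) == pytest.approx(2.22, abs=5e-3)

    def test_mismatched_plot_sets_rejected(self):
        rows = self.table_row(53, {16: 800}, 812) + [
            dict(plot_id="C", dap=53, patch_size=24, leaf_count_used=np.nan,
                 estimate=10, truth=10)
        ]
        with pytest.raises(ValueError):
            sc.evaluate_estimates(pd.DataFrame(rows))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            sc.evaluate_estimates(pd.DataFrame({"estimate": [1]}))


class TestCoefficientVsDap:
    def test_printed_coefficients_decline_with_dap(self):
        daps = (32, 39, 46, 53, 58, 68)
        coefs = (0.354, 0.297, 0.322, 0.277, 0.220, 0.214)
        models = [
            sc.LeafToPlantResults(slope=a, intercept=0, r2_loocv=1, mae=0,
                                  rmse=0, n_folds=6, dap=d)
            for d, a in zip(daps, coefs)
        ]
        trend = sc.fit_coefficient_vs_dap(models)
        assert trend.slope < 0

    def test_two_models_fit_exactly(self):
        models = [
            sc.LeafToPlantResults(slope=a, intercept=0, r2_loocv=1, mae=0,
                                  rmse=0, n_folds=6, dap=d)
            for d, a in ((32, 0.3), (68, 0.2))
        ]
        assert sc.fit_coefficient_vs_dap(models).r_squared == pytest.approx(1.0)

    def test_constant_coefficients_give_zero_slope(self):
        models = [
            sc.LeafToPlantResults(slope=0.25, intercept=0, r2_loocv=1, mae=0,
                                  rmse=0, n_folds=6, dap=d)
            for d in (32, 46, 68)
        ]
        assert sc.fit_coefficient_vs_dap(models).slope == 0.0
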