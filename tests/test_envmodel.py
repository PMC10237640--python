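"""Model objects, stepwise selection, redundancy pruning, effect shapes."""

import numpy as np
import pandas as pd
import pytest

from nearshore_overlap.envmodel import (AdditiveCountModel, classify_effect_shape,
                                        redundancy_prune, select_smoothing,
                                        stepwise_select)


def selection_data(seed, n=500, n_noise=7):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(n_noise)})
    data["sst"] = rng.uniform(12, 22, n)
    data["wave_height"] = rng.uniform(0.2, 2.5, n)
    data["wind_speed"] = rng.uniform(0, 8, n)
    eta = (0.5 + 0.12 * (data["sst"] - 17)
           - 0.8 * (data["wave_height"] - 1.0) ** 2
           - 0.15 * (data["wind_speed"] - 4))
    data["y"] = rng.poisson(np.exp(eta))
    return data


class TestModelObjects:
    def test_from_dataframe_validates_columns(self):
        data = pd.DataFrame({"y": [1, 2], "x": [0.1, 0.2]})
        with pytest.raises(KeyError):
            AdditiveCountModel.from_dataframe(data, "y", smooth=["missing"])

    def test_missing_covariates_rejected(self):
        data = pd.DataFrame({"y": [1, 2, 3], "x": [0.1, np.nan, 0.3]})
        with pytest.raises(ValueError):
            AdditiveCountModel.from_dataframe(data, "y", smooth=["x"])

    def test_summary_reports_terms_and_edf(self):
        data = selection_data(0)
        res = AdditiveCountModel.from_dataframe(
            data, "y", smooth=["sst", "wave_height"]).fit()
        text = res.summary()
        assert "sst" in text and "wave_height" in text
        assert "AIC" in text

    def test_mean_anchored_curve_definition(self):
        """Single-covariate model: curve equals exp(intercept + f_hat) pointwise."""
        data = selection_data(1)
        res = AdditiveCountModel.from_dataframe(data, "y", smooth=["sst"]).fit()
        xg, curve = res.mean_anchored_curve("sst")
        _, f = res.partial_effect("sst", x=xg)
        assert curve == pytest.approx(np.exp(res.fit.coef[0] + f))

    def test_intercept_only_model_predicts_mean_response(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"y": rng.poisson(3.0, 200),
                             "x": rng.uniform(0, 1, 200)})
        res = AdditiveCountModel.from_dataframe(data, "y", smooth=[]).fit()
        assert np.ptp(res.fittedvalues) == pytest.approx(0.0, abs=1e-10)
        assert res.fittedvalues[0] == pytest.approx(data["y"].mean(), rel=1e-6)

    def test_absent_term_rejected(self):
        data = selection_data(3)
        res = AdditiveCountModel.from_dataframe(data, "y", smooth=["sst"]).fit()
        with pytest.raises(KeyError):
            res.mean_anchored_curve("wave_height")

    def test_parabolic_wave_height_optimum_recovered(self):
        data = selection_data(4, n=800)
        res = AdditiveCountModel.from_dataframe(data, "y",
                                                smooth=["wave_height"]).fit()
        xg, curve = res.mean_anchored_curve("wave_height", n_points=200)
        assert xg[np.argmax(curve)] == pytest.approx(1.0, abs=0.2)


class TestSmoothingSelection:
    def test_linear_truth_gets_heavier_penalty_than_parabolic(self):
        data = selection_data(20, n=800)
        alphas = select_smoothing(data, "y", ["sst", "wave_height"])
        assert alphas["sst"] > alphas["wave_height"]

    def test_per_term_alphas_accepted_by_model(self):
        data = selection_data(21)
        alphas = select_smoothing(data, "y", ["sst"])
        res = AdditiveCountModel.from_dataframe(data, "y", smooth=["sst"],
                                                alpha=alphas).fit()
        assert res.fit.converged


class TestStepwise:
    def test_forced_terms_respected(self):
        data = selection_data(5)
        out = stepwise_select(data, "y", ["n0", "n1"], forced=["sst"])
        assert "sst" in out["selected"]

    def test_aic_non_increasing_along_path(self):
        data = selection_data(6)
        out = stepwise_select(data, "y",
                              ["sst", "wave_height", "wind_speed", "n0", "n1"])
        aics = [a for _, a in out["trace"]]
        assert all(a >= b for a, b in zip(aics, aics[1:]))

    def test_strong_signal_found(self):
        data = selection_data(7)
        out = stepwise_select(data, "y",
                              ["sst", "wave_height", "wind_speed",
                               "n0", "n1", "n2", "n3"])
        assert {"sst", "wave_height"} <= set(out["selected"])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            stepwise_select(selection_data(8), "y", [])


class TestRedundancyPrune:
    def test_duplicated_covariate_keeps_higher_importance(self):
        data = selection_data(9)
        data["sst_copy"] = data["sst"] + np.random.default_rng(9).normal(0, 1e-3, len(data))
        out = redundancy_prune(data, "y", ["sst", "sst_copy", "wave_height"])
        survivors = set(out["final"])
        assert len({"sst", "sst_copy"} & survivors) == 1
        assert "wave_height" in survivors

    def test_seasonal_exception_pair_retained(self):
        rng = np.random.default_rng(10)
        n = 400
        month = rng.integers(1, 13, n).astype(float)
        sst = 14 + 4 * np.sin(2 * np.pi * (month - 4) / 12) + rng.normal(0, 0.3, n)
        data = pd.DataFrame({"month": month, "sst": sst})
        data["y"] = rng.poisson(np.exp(0.5 + 0.1 * (sst - 16)))
        assert abs(np.corrcoef(month, sst)[0, 1]) < 1  # correlated but not identical
        out = redundancy_prune(data, "y", ["month", "sst"])
        assert {"month", "sst"} <= set(out["final"])

    def test_sst_anomaly_never_dropped(self):
        rng = np.random.default_rng(11)
        n = 400
        anom = rng.normal(0, 1, n)
        proxy = anom + rng.normal(0, 0.1, n)
        data = pd.DataFrame({"sst_anomaly": anom, "proxy": proxy})
        data["y"] = rng.poisson(np.exp(0.5 + 0.3 * proxy))
        out = redundancy_prune(data, "y", ["sst_anomaly", "proxy"])
        assert "sst_anomaly" in out["final"]

    def test_correlated_wave_periods_pruned_by_importance(self):
        rng = np.random.default_rng(12)
        n = 500
        mean_period = rng.uniform(5, 14, n)
        peak_period = mean_period * 1.2 + rng.normal(0, 1.0, n)
        data = pd.DataFrame({"mean_wave_period": mean_period,
                             "peak_wave_period": peak_period})
        data["y"] = rng.poisson(np.exp(0.5 + 0.15 * (mean_period - 9)))
        assert np.corrcoef(mean_period, peak_period)[0, 1] > 0.7
        out = redundancy_prune(data, "y", ["mean_wave_period", "peak_wave_period"])
        assert out["final"] == ["mean_wave_period"]
        assert out["dropped"] == ["peak_wave_period"]


class TestEffectShapes:
    xg = np.linspace(0, 1, 100)

    def test_monotone_labels(self):
        assert classify_effect_shape(self.xg, self.xg) == "+"
        assert classify_effect_shape(self.xg, -2 * self.xg) == "-"

    def test_single_peak_is_p(self):
        assert classify_effect_shape(self.xg, -((self.xg - 0.5) ** 2)) == "p"

    def test_multimodal_is_q(self):
        assert classify_effect_shape(self.xg, np.sin(3 * np.pi * self.xg)) == "q"

    def test_flat_is_zero_label(self):
        f = np.full_like(self.xg, 0.001)
        assert classify_effect_shape(self.xg, f, response_scale=10.0) == "0"

    def test_affine_rescaling_invariance(self):
        f = -((self.xg - 0.5) ** 2)
        assert classify_effect_shape(5 + 20 * self.xg, f) == \
            classify_effect_shape(self.xg, f)

    def test_small_wiggle_does_not_flip_monotone(self):
        f = self.xg + 0.005 * np.sin(10 * np.pi * self.xg)
        assert classify_effect_shape(self.xg, f) == "+"

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            classify_effect_shape(np.linspace(0, 1, 10), np.linspace(0, 1, 10))
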