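"""Plate layout, blank correction, logistic fits, beta regression."""

import numpy as np
import pandas as pd
import pytest

from coferm.screening import (
    PlateLayout,
    beta_from_fit,
    beta_regression,
    blank_correct,
    fit_growth_curve,
    GrowthCurveFit,
    screen_plate,
    well_id,
)
from coferm.synth import ScenarioSpec, gen_plate, true_plate_params
from helpers import ols_normal_equations


def logistic_y(t, A, mu, lam):
    return A / (1.0 + np.exp(4.0 * mu / A * (lam - t) + 2.0))


class TestLayout:
    def test_default_follows_plate_scheme(self):
        layout = PlateLayout.default()
        roles = pd.Series([i.role for i in layout.wells.values()])
        assert roles.value_counts().to_dict() == {
            "growth": 60, "medium_blank": 30, "water_blank": 10,
        }
        # 4 replicate growth wells per (sugar, lignin) condition
        conds = pd.Series(
            [(i.sugar_variant, i.lignin_level)
             for i in layout.wells.values() if i.role == "growth"]
        )
        assert set(conds.value_counts()) == {4}
        # two medium-blank wells per condition
        assert len(layout.blanks_for("xyl60", 0.4)) == 2

    def test_toml_round_trip(self, tmp_path):
        layout = PlateLayout.default()
        path = tmp_path / "layout.toml"
        layout.to_toml(path)
        back = PlateLayout.from_toml(path)
        assert back.to_dict() == layout.to_dict()


class TestBlankCorrect:
    def _long(self, curves: dict) -> pd.DataFrame:
        t = np.arange(0, 10.0, 0.5)
        return pd.concat(
            [pd.DataFrame({"well": w, "t_h": t, "od": od(t)}) for w, od in curves.items()],
            ignore_index=True,
        )

    def test_growth_equal_to_blanks_gives_flat_zero(self):
        layout = PlateLayout.default()
        base = lambda t: np.full_like(t, 0.1)
        curves = {well_id(1, c): base for c in (1, 5, 6)}
        corr, floored = blank_correct(self._long(curves), layout)
        assert np.allclose(corr["od"], 0.0)

    def test_constant_blank_additivity(self):
        layout = PlateLayout.default()
        sig = lambda t: logistic_y(t, 1.5, 0.6, 2.0)
        curves = {
            well_id(1, 1): lambda t: np.full_like(t, 0.1),
            well_id(1, 5): lambda t: 0.1 + sig(t),
        }
        corr, _ = blank_correct(self._long(curves), layout)
        t = corr["t_h"].to_numpy()
        assert np.allclose(corr["od"], sig(t), atol=1e-12)

    def test_drifting_blank_removed_on_synthetic_plate(self):
        spec = ScenarioSpec(seed=0, od_noise=0.0)
        od_long, layout, truth = gen_plate(spec)
        corr, floored = blank_correct(od_long, layout)
        g = corr[corr.well == well_id(1, 5)].sort_values("t_h")
        p = true_plate_params("glc60", 0.0)
        cells = truth["od0_cells"] * np.exp(
            logistic_y(g["t_h"].to_numpy(), p["A"], p["mu_max"], p["lam"])
        )
        assert np.max(np.abs(g["od"].to_numpy() - cells)) < 1e-9
        assert floored == 0

    def test_missing_blank_names_condition(self):
        layout = PlateLayout.default()
        df = self._long({well_id(1, 5): lambda t: np.full_like(t, 0.2)})
        with pytest.raises(ValueError, match="glc60"):
            blank_correct(df, layout)


class TestFitGrowthCurve:
    def test_self_inverse_on_formula_generated_curve(self):
        t = np.arange(0, 24.0, 0.25)
        y = logistic_y(t, 2.0, 0.5, 3.0)
        fit = fit_growth_curve(t, y, log_input=True)
        assert fit.A == pytest.approx(2.0, abs=1e-6)
        assert fit.mu_max == pytest.approx(0.5, abs=1e-6)
        assert fit.lam == pytest.approx(3.0, abs=1e-6)

    def test_flat_curve_flagged_no_growth(self):
        t = np.arange(0, 12.0, 0.5)
        fit = fit_growth_curve(t, np.full_like(t, 0.01))
        assert fit.flags == ["no growth"]
        assert fit.A == 0.0 and fit.mu_max == 0.0 and fit.lam == t[-1]

    def test_time_shift_moves_lag_only(self):
        t = np.arange(0, 30.0, 0.25)
        od = 0.06 * np.exp(logistic_y(t, 2.2, 0.45, 2.5))
        f0 = fit_growth_curve(t, od)
        f1 = fit_growth_curve(t + 4.0, od)
        assert f1.lam - f0.lam == pytest.approx(4.0, abs=1e-3)
        assert f1.A == pytest.approx(f0.A, rel=1e-4)
        assert f1.mu_max == pytest.approx(f0.mu_max, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_growth_curve([0, 1, 2], [0.1, 0.2, 0.3])


class TestBeta:
    def test_no_growth_beta_zero_under_every_definition(self):
        fit = GrowthCurveFit(0.0, 0.0, 24.0, 0.0, flags=["no growth"])
        for d in ("mu_max", "A*mu_max", "A"):
            assert beta_from_fit(fit, d) == 0.0

    def test_product_definition_arithmetic(self):
        fit = GrowthCurveFit(2.0, 0.5, 3.0, 0.0)
        assert beta_from_fit(fit, "A*mu_max") == 1.0
        assert beta_from_fit(fit) == 0.5

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError, match="unknown beta"):
            beta_from_fit(GrowthCurveFit(1, 1, 1, 0), "mu*lam")


class TestBetaRegression:
    def test_exact_line(self):
        L = np.array([0.0, 0.2, 0.4, 0.6])
        reg = beta_regression(L, 0.4 - 0.5 * L)
        assert reg["slope"] == pytest.approx(-0.5, abs=1e-12)
        assert reg["intercept"] == pytest.approx(0.4, abs=1e-12)
        assert reg["x_intercept"] == pytest.approx(0.8, rel=1e-10)
        assert reg["r2"] == pytest.approx(1.0)

    def test_positive_slope_flagged_no_tolerance(self):
        reg = beta_regression([0, 0.4, 0.8], [0.1, 0.2, 0.3])
        assert np.isnan(reg["x_intercept"])
        assert reg["flags"]

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 12)
        y = 0.5 - 0.3 * x + rng.normal(0, 0.05, 12)
        reg = beta_regression(x, y)
        slope, intercept = ols_normal_equations(x, y)
        assert reg["slope"] == pytest.approx(slope, abs=1e-12)
        assert reg["intercept"] == pytest.approx(intercept, abs=1e-12)

    def test_exclusion_mask_drops_points(self):
        # an outlier at the highest lignin level is excluded, as in
        # screening practice where no-growth wells distort the line
        L = np.array([0.0, 0.2, 0.4, 0.8])
        beta = np.array([0.4, 0.3, 0.2, 0.9])
        reg = beta_regression(L, beta, exclude=[False, False, False, True])
        assert reg["slope"] == pytest.approx(-0.5, abs=1e-12)
        assert reg["n_used"] == 3

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError, match="included"):
            beta_regression([0, 0.2], [1, 2], exclude=[True, True])


class TestScreenPlateSubset:
    def test_replicate_aggregation_permutation_invariant(self):
        spec = ScenarioSpec(seed=4)
        od_long, layout, _ = gen_plate(spec)
        keep = [well_id(r, c) for r in (1, 2) for c in (1, 5, 6)] \
            + [well_id(r, c) for r in (9, 10) for c in (1, 5, 6)]
        sub = od_long[od_long.well.isin(keep)]
        res1 = screen_plate(sub, layout)
        shuffled = sub.sample(frac=1.0, random_state=0)
        res2 = screen_plate(shuffled, layout)
        pd.testing.assert_frame_equal(res1["per_condition"], res2["per_condition"])
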