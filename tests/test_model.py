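"""Cofermentation ODE model: rate laws, integration, stop rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coferm.model import (
    FermentState,
    MonodParams,
    Trajectory,
    fermentation_time,
    simulate,
    specific_rates,
)
from conftest import random_params
from helpers import euler_simulate, rk4_simulate


class TestSpecificRates:
    def test_no_substrate_no_growth(self, std_params):
        mu_i, mu = specific_rates(FermentState(0, 1.0, 0, 0, 0, 0, 0), std_params)
        assert mu == 0.0
        assert all(v == 0.0 for v in mu_i.values())

    def test_monod_saturation_limit(self, std_params):
        state = FermentState(0, 1.0, 1e9, 0, 0, 0, 0)
        mu_i, _ = specific_rates(state, std_params)
        assert mu_i["glc"] == pytest.approx(std_params.mu_max_glc, rel=1e-6)

    def test_half_saturation_with_half_lignin_inhibition(self, std_params):
        # S_glc = K_S and L = K_L: 0.5 saturation x 0.5 lignin factor
        state = FermentState(
            0, 1.0, std_params.K_S_glc, 0, 0, 0, std_params.K_L
        )
        _, mu = specific_rates(state, std_params)
        assert mu == pytest.approx(std_params.mu_max_glc / 4, rel=1e-12)

    def test_catabolite_repression_scales_pentose_rates(self, std_params):
        s = FermentState(0, 1.0, std_params.K_rep, 1e9, 0, 0, 0)
        mu_i, _ = specific_rates(s, std_params)
        # saturating xylose at S_glc = K_rep: repression halves the rate
        assert mu_i["xyl"] == pytest.approx(std_params.mu_max_xyl / 2, rel=1e-6)

    def test_non_finite_state_rejected(self, std_params):
        with pytest.raises(ValueError, match="non-finite"):
            specific_rates(FermentState(0, np.nan, 1, 1, 1, 0, 0), std_params)

    def test_negative_concentration_rejected(self, std_params):
        with pytest.raises(ValueError, match="negative"):
            specific_rates(FermentState(0, -0.1, 1, 1, 1, 0, 0), std_params)


class TestSimulate:
    def test_no_inoculum_stays_constant(self, std_params):
        init = FermentState(0, 0.0, 40, 20, 10, 0, 1.0)
        traj = simulate(std_params, init, np.linspace(0, 24, 25))
        assert np.allclose(traj.data.iloc[-1, 1:], traj.data.iloc[0, 1:])

    def test_single_sugar_mass_coupling(self, std_params):
        init = FermentState(0, 0.05, 20.0, 0, 0, 0, 0)
        traj = simulate(std_params, init, np.linspace(0, 40, 41))
        d = traj.data
        dX = d.X_gL.iloc[-1] - d.X_gL.iloc[0]
        dS = d.glc_gL.iloc[0] - d.glc_gL.iloc[-1]
        assert dX == pytest.approx(std_params.Y_XS_glc * dS, abs=1e-5)

    def test_diauxie_delay_monotone_in_K_rep(self, std_params):
        """Stronger repression (smaller K_rep) delays xylose consumption."""
        init = FermentState(0, 0.05, 20.0, 10.0, 0, 0, 0)
        t = np.arange(0, 30.001, 0.25)

        def t50(k_rep):
            p = std_params.replace(K_rep=k_rep)
            d = simulate(p, init, t).data
            half = 0.5 * d.xyl_gL.iloc[0]
            return d.t_h[d.xyl_gL <= half].iloc[0], d

        t50_glc = None
        prev = -np.inf
        for k in (2.0, 0.5, 0.1):
            tx, d = t50(k)
            half_glc = 0.5 * d.glc_gL.iloc[0]
            tg = d.t_h[d.glc_gL <= half_glc].iloc[0]
            assert tx > tg  # xylose always trails glucose
            assert tx > prev  # and trails further as K_rep shrinks
            prev = tx

    def test_adaptive_integrator_agrees_with_euler_brute_force(self, std_params):
        init = FermentState(0, 0.05, 20.0, 10.0, 0, 0, 0)
        t = np.linspace(0, 12, 13)
        prod = simulate(std_params, init, t).data.iloc[-1, 1:5].to_numpy(float)
        brute = euler_simulate(std_params, init, t, dt=1e-3)[-1, :4]
        scale = np.maximum(np.abs(brute), 0.1)
        assert np.all(np.abs(prod - brute) / scale < 5e-3)

    def test_rk4_oracle_equivalence(self, std_params):
        p = std_params.replace(alpha_glc=10.0, alpha_xyl=10.0, beta_LP=0.02)
        init = FermentState(0, 0.05, 20.0, 10.0, 2.0, 0, 0.5)
        t = np.linspace(0, 12, 25)
        prod = simulate(p, init, t).data.iloc[:, 1:].to_numpy(float)
        oracle = rk4_simulate(p, init, t, dt=1e-3)
        denom = np.maximum(np.abs(oracle), 1e-2)
        assert np.max(np.abs(prod - oracle) / denom) < 1e-3

    def test_grid_must_start_at_init_time(self, std_params):
        init = FermentState(0, 0.05, 20, 0, 0, 0, 0)
        with pytest.raises(ValueError, match="start at init.t"):
            simulate(std_params, init, [1.0, 2.0])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegativity_and_mass_coupling_random_draws(self, seed):
        """Random plausible kinetics: states stay >= 0 and, without
        product formation, biomass gain equals yield-weighted sugar use."""
        rng = np.random.default_rng(seed)
        p = random_params(rng).replace(
            alpha_glc=0.0, alpha_xyl=0.0, alpha_ara=0.0, beta_LP=0.0
        )
        init = FermentState(0, 0.05, 30.0, 15.0, 8.0, 0.0, rng.uniform(0, 2))
        traj = simulate(p, init, np.linspace(0, 48, 25))
        d = traj.data
        assert (d.iloc[:, 1:].to_numpy() >= 0).all()
        dX = d.X_gL.iloc[-1] - d.X_gL.iloc[0]
        coupled = (
            p.Y_XS_glc * (d.glc_gL.iloc[0] - d.glc_gL.iloc[-1])
            + p.Y_XS_xyl * (d.xyl_gL.iloc[0] - d.xyl_gL.iloc[-1])
            + p.Y_XS_ara * (d.ara_gL.iloc[0] - d.ara_gL.iloc[-1])
        )
        assert dX == pytest.approx(coupled, abs=1e-4)

    def test_biomass_monotone_nonincreasing_in_lignin(self, std_params):
        init = lambda L: FermentState(0, 0.05, 30.0, 15.0, 8.0, 0.0, L)
        t = np.linspace(0, 36, 19)
        prev = None
        for L in (0.0, 0.625, 1.25, 2.5, 3.75):
            X = simulate(std_params, init(L), t).data.X_gL.to_numpy()
            if prev is not None:
                assert np.all(X <= prev + 1e-8)
            prev = X


class TestFermentationTime:
    def _traj(self, t, glc):
        df = pd.DataFrame({
            "t_h": t, "X_gL": 1.0, "glc_gL": glc, "xyl_gL": 0.0,
            "ara_gL": 0.0, "la_gL": 0.0, "lignin_gL": 0.0,
        })
        return Trajectory(df, "observed")

    def test_sugar_exhausted_on_grid(self):
        t = np.arange(0, 49, 2.0)
        glc = np.maximum(46.0 - 46.0 / 26.0 * t, 0.0)  # hits 0 at t = 26
        assert fermentation_time(self._traj(t, glc)) == 26.0

    def test_sugars_never_depleted_gives_last_time(self):
        t = np.arange(0, 49, 2.0)
        assert fermentation_time(self._traj(t, np.full_like(t, 30.0))) == 48.0

    def test_infinite_threshold_degenerates_to_first_point(self):
        t = np.arange(0, 49, 2.0)
        traj = self._traj(t, np.full_like(t, 30.0))
        assert fermentation_time(traj, threshold=np.inf) == 0.0

    def test_harvest_rule_returns_last_time(self):
        t = np.arange(0, 49, 2.0)
        traj = self._traj(t, np.zeros_like(t))
        assert fermentation_time(traj, rule="harvest") == 48.0


class TestMonodParams:
    def test_json_round_trip_lossless(self, std_params, tmp_path):
        path = tmp_path / "p.json"
        std_params.to_json(path)
        assert MonodParams.from_json(path) == std_params

    def test_toml_round_trip_lossless(self, std_params, tmp_path):
        path = tmp_path / "p.toml"
        p = std_params.replace(alpha_glc=11.2, use_product_inhibition=False)
        p.to_toml(path)
        assert MonodParams.from_toml(path) == p

    def test_unknown_key_rejected(self, std_params):
        d = std_params.to_dict()
        d["delta"] = 1.0
        with pytest.raises(ValueError, match="unknown parameter"):
            MonodParams.from_dict(d)

    @pytest.mark.parametrize(
        "bad", [{"mu_max_glc": -0.1}, {"Y_XS_glc": 1.5}, {"n_P": -1.0}, {"K_L": 0.0}]
    )
    def test_invalid_values_rejected(self, std_params, bad):
        with pytest.raises(ValueError):
            std_params.replace(**bad)
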