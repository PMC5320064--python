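"""Synthetic study data with known ground truth.

Generates the three kinds of raw data the analysis pipeline consumes, at
the scales of the study conditions, so every stage runs end-to-end and
recovery of programmed truth can be tested:

* fermentation time series — simulated from a strain preset of the
  cofermentation model (initial sugars ~46/21/10.6 g/L glucose/xylose/
  arabinose for the artificial medium, ~7/2.5/0.5 g/L for hydrolysate
  scale; lignin levels 0-3.75 g/L), sampled on a 2 h grid with
  multiplicative lognormal noise plus an additive floor emulating HPLC
  precision;
* honeycomb-plate OD curves — 100 wells laid out per the screening
  scheme (blank columns, water column, 4 replicate growth wells per
  sugar x lignin condition at 0-0.8 g/L lignin), logistic growth whose
  true mu_max declines linearly to zero at a programmed lignin tolerance,
  drifting medium blanks, additive OD noise;
* UV spectra (250-400 nm) — Gaussian compound peaks over a small medium
  baseline, attenuated by programmed uptake fractions at 2.5 h and 5 h.

Strain presets are order-of-magnitude matches to the published
fermentation scales (maximum biomass ~5-8 g/L, lactate ~65-70 g/L in the
artificial medium, near-homolactic yields), not fitted constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import FermentState, MonodParams, Trajectory, simulate
from .screening import (
    PlateLayout,
    SCREEN_LIGNIN_LEVELS,
    SUGAR_VARIANTS,
)

FERMENT_LIGNIN_LEVELS = (0.0, 0.625, 1.25, 2.5, 3.75)

#: initial sugar concentrations (glc, xyl, ara) in g/L
SUGAR_PRESETS = {
    "AM": (46.0, 21.0, 10.6),
    "hydrolysate": (7.0, 2.5, 0.5),
}

#: kinetic presets per strain archetype (g/L, 1/h, g/g)
STRAIN_PRESETS = {
    # fast strain: complete consumption in ~26 h, near-homolactic yield,
    # strongly slowed (but not stopped) by sub-g/L lignin
    "dsm2314": MonodParams(
        mu_max_glc=0.30, mu_max_xyl=0.165, mu_max_ara=0.126,
        K_S_glc=0.5, K_S_xyl=0.8, K_S_ara=1.0,
        Y_XS_glc=0.078, Y_XS_xyl=0.078, Y_XS_ara=0.078,
        K_rep=2.0, K_L=0.6, P_max=80.0, n_P=1.0,
        alpha_glc=11.2, alpha_xyl=11.2, alpha_ara=11.2, beta_LP=0.02,
    ),
    # intermediate strain: lower biomass yield, high lactate per biomass
    "id14_298": MonodParams(
        mu_max_glc=0.28, mu_max_xyl=0.14, mu_max_ara=0.10,
        K_S_glc=0.6, K_S_xyl=1.0, K_S_ara=1.2,
        Y_XS_glc=0.056, Y_XS_xyl=0.056, Y_XS_ara=0.056,
        K_rep=1.5, K_L=0.7, P_max=80.0, n_P=1.0,
        alpha_glc=15.5, alpha_xyl=15.5, alpha_ara=15.5, beta_LP=0.02,
    ),
    # strongly glucose-repressed, product-limited strain: stalls near
    # 47 g/L lactate leaving pentose residuals at 48 h; lignin-tolerant
    "id14_301": MonodParams(
        mu_max_glc=0.30, mu_max_xyl=0.10, mu_max_ara=0.07,
        K_S_glc=0.7, K_S_xyl=1.2, K_S_ara=1.5,
        Y_XS_glc=0.068, Y_XS_xyl=0.068, Y_XS_ara=0.068,
        K_rep=0.3, K_L=2.5, P_max=52.0, n_P=1.5,
        alpha_glc=9.0, alpha_xyl=9.0, alpha_ara=9.0, beta_LP=0.015,
    ),
}

#: plate-screening truth: per sugar variant (A, mu_max at 0 lignin,
#: programmed lignin tolerance g/L, lag at 0 lignin, lag slope h per g/L)
PLATE_TRUTH = {
    "glc60": {"A": 2.5, "mu0": 0.55, "lignin_tol": 1.20, "lam0": 2.0, "lam_slope": 2.5},
    "xyl60": {"A": 2.2, "mu0": 0.40, "lignin_tol": 0.90, "lam0": 2.5, "lam_slope": 2.5},
    "glc40_xyl20": {"A": 2.4, "mu0": 0.50, "lignin_tol": 1.05, "lam0": 2.2, "lam_slope": 2.5},
}

#: UV peak shapes per compound: center (nm), width (nm), height (AU)
SPECTRA_TRUTH = {
    "AL": {"center": 280.0, "width": 18.0, "height": 1.2},
    "FA": {"center": 316.0, "width": 14.0, "height": 0.95},
    "VAN": {"center": 307.0, "width": 13.0, "height": 1.0},
}


@dataclass
class ScenarioSpec:
    """Everything needed to regenerate one synthetic dataset exactly."""

    seed: int = 0
    strain: str = "dsm2314"
    sugar_preset: str = "AM"
    lignin_levels: tuple = FERMENT_LIGNIN_LEVELS
    sigma_rel: float = 0.02       # multiplicative lognormal noise, series
    noise_floor_gL: float = 0.05  # additive noise floor, series
    od_noise: float = 0.01        # additive OD noise (AU), plate
    spectra_noise: float = 0.0    # additive absorbance noise (AU)
    t_end_h: float = 48.0
    dt_h: float = 2.0
    X0_gL: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.noise_floor_gL < 0 or self.od_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if self.strain not in STRAIN_PRESETS:
            raise ValueError(f"unknown strain preset {self.strain!r}")
        if self.sugar_preset not in SUGAR_PRESETS:
            raise ValueError(f"unknown sugar preset {self.sugar_preset!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lignin_levels"] = list(self.lignin_levels)
        return d


def _embed(df: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    df.attrs["scenario"] = spec.to_dict()
    return df


def gen_fermentation(spec: ScenarioSpec, lignin_gL: float = 0.0):
    """One noisy fermentation series plus its hidden truth.

    Returns ``(observed DataFrame, truth)`` where truth holds the preset
    MonodParams, the noise-free Trajectory and the scenario itself.
    """
    params = STRAIN_PRESETS[spec.strain]
    s0 = SUGAR_PRESETS[spec.sugar_preset]
    init = FermentState(0.0, spec.X0_gL, s0[0], s0[1], s0[2], 0.0, lignin_gL)
    t_grid = np.arange(0.0, spec.t_end_h + 1e-9, spec.dt_h)
    traj = simulate(params, init, t_grid)

    rng = np.random.default_rng(spec.seed)
    obs = traj.data.copy()
    for col in ("X_gL", "glc_gL", "xyl_gL", "ara_gL", "la_gL"):
        truth_v = obs[col].to_numpy()
        mult = rng.lognormal(0.0, spec.sigma_rel, size=len(truth_v)) if spec.sigma_rel > 0 else 1.0
        add = rng.normal(0.0, spec.noise_floor_gL, size=len(truth_v)) if spec.noise_floor_gL > 0 else 0.0
        obs[col] = np.maximum(truth_v * mult + add, 0.0)
    obs = _embed(obs, spec)
    truth = {"params": params, "trajectory": traj, "scenario": spec, "lignin_gL": lignin_gL}
    return obs, truth


def true_plate_params(sugar: str, lignin: float) -> dict:
    """Programmed (A, mu_max, lam) for one screening condition."""
    t = PLATE_TRUTH[sugar]
    mu = t["mu0"] * max(0.0, 1.0 - lignin / t["lignin_tol"])
    return {"A": t["A"], "mu_max": mu, "lam": t["lam0"] + t["lam_slope"] * lignin}


def _logistic_y(t, A, mu, lam):
    if mu <= 0 or A <= 0:
        return np.zeros_like(t)
    z = np.clip(4.0 * mu / A * (lam - t) + 2.0, -500, 500)
    return A / (1.0 + np.exp(z))


def gen_plate(spec: ScenarioSpec):
    """Synthetic honeycomb-plate OD curves per the screening scheme.

    Returns ``(od long DataFrame, PlateLayout, truth)`` where truth maps
    (sugar_variant, lignin) to the programmed logistic parameters. Medium
    blanks carry a baseline with slow evaporation drift and a small
    lignin absorbance term; growth wells add cell turbidity
    OD0 * exp(y(t)) on top of the same background.
    """
    layout = PlateLayout.default()
    rng = np.random.default_rng(spec.seed)
    # 15-min turbidimeter interval; the run lasts until the slowest
    # near-tolerance condition reaches stationary phase
    t = np.arange(0.0, 72.0 + 1e-9, 0.25)
    od0_cells = 0.06
    rows = []
    for w, info in sorted(layout.wells.items()):
        if info.role == "water_blank":
            base = 0.04 + 0.0005 * t
        else:
            base = 0.08 + 0.001 * t + 0.05 * (info.lignin_level or 0.0)
        od = base.copy()
        if info.role == "growth":
            p = true_plate_params(info.sugar_variant, info.lignin_level)
            od = od + od0_cells * np.exp(_logistic_y(t, p["A"], p["mu_max"], p["lam"]))
        if spec.od_noise > 0:
            od = od + rng.normal(0.0, spec.od_noise, size=len(t))
        od = np.maximum(od, 0.0)
        rows.append(pd.DataFrame({"well": w, "t_h": t, "od": od}))
    od_long = _embed(pd.concat(rows, ignore_index=True), spec)
    truth = {
        (sugar, lig): true_plate_params(sugar, lig)
        for sugar in SUGAR_VARIANTS
        for lig in SCREEN_LIGNIN_LEVELS
    }
    truth["lignin_tolerance"] = {s: PLATE_TRUTH[s]["lignin_tol"] for s in SUGAR_VARIANTS}
    truth["od0_cells"] = od0_cells
    truth["scenario"] = spec
    return od_long, layout, truth


def gen_spectra(spec: ScenarioSpec, uptake: tuple[float, float] = (0.2, 0.5)):
    """Blank / 2.5 h / 5 h UV spectrum triples for AL, FA and vanillin.

    ``uptake`` gives the fraction of the compound peak removed at the two
    sampling times; zero uptake yields identical spectra. Returns
    ``(spectra, truth)`` with spectra[compound][label] a Spectrum.
    """
    from .decolorization import Spectrum

    f25, f50 = uptake
    if not (0 <= f25 <= 1 and 0 <= f50 <= 1):
        raise ValueError("uptake fractions must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    wl = np.arange(250.0, 400.0 + 0.5, 1.0)
    baseline = 0.003  # residual medium (ATP + yeast extract) absorbance
    spectra: dict[str, dict] = {}
    for comp, shape in SPECTRA_TRUTH.items():
        peak = shape["height"] * np.exp(
            -0.5 * ((wl - shape["center"]) / shape["width"]) ** 2
        )
        triple = {}
        for label, frac in (("blank", 0.0), ("t2.5h", f25), ("t5h", f50)):
            a = baseline + (1.0 - frac) * peak
            if spec.spectra_noise > 0:
                a = a + rng.normal(0.0, spec.spectra_noise, size=len(wl))
            triple[label] = Spectrum(wl, np.maximum(a, 0.0), label, comp, spec.strain)
        spectra[comp] = triple
    truth = {"uptake": {"t2.5h": f25, "t5h": f50}, "baseline": baseline,
             "shapes": SPECTRA_TRUTH, "scenario": spec}
    return spectra, truth
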