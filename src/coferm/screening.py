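"""High-throughput optical-density screening of lignin endurance.

A 100-well honeycomb plate (Bioscreen C, 10 rows x 10 columns, wide-band
420-580 nm filter) screens three sugar media (60 g/L glucose, 60 g/L
xylose, 40 g/L glucose + 20 g/L xylose) against five alkali-lignin
levels (0.0-0.8 g/L):

* columns 1-3: medium blanks, one column per sugar medium, two wells per
  lignin level going down the rows;
* column 4: water blank;
* columns 5-10: growth wells — two columns per sugar medium, two rows per
  lignin level, i.e. 4 replicate wells per (sugar, lignin) condition.

Blank-corrected curves are fitted in log-growth form
``y(t) = ln(OD(t)/OD(0))`` with the modified (Zwietering-style) logistic

    y(t) = A / (1 + exp(4*mu_max/A * (lam - t) + 2))

whose parameters are the asymptote A, the maximum specific growth rate
mu_max (1/h) and the lag time lam (h). A composite growth parameter beta
(by default simply mu_max) is regressed linearly on the lignin level;
the regression's x-intercept extrapolates the lignin tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

SUGAR_VARIANTS = ("glc60", "xyl60", "glc40_xyl20")
SCREEN_LIGNIN_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8)

#: growth columns (1-based) per sugar variant and blank column per variant
GROWTH_COLS = {"glc60": (5, 6), "xyl60": (7, 8), "glc40_xyl20": (9, 10)}
BLANK_COL = {"glc60": 1, "xyl60": 2, "glc40_xyl20": 3}
WATER_COL = 4


def well_id(row: int, col: int) -> str:
    return f"R{row:02d}C{col:02d}"


@dataclass
class WellInfo:
    role: str  # medium_blank | water_blank | growth
    sugar_variant: str | None = None
    lignin_level: float | None = None


class PlateLayout:
    """Well -> role / sugar / lignin mapping for one honeycomb plate."""

    def __init__(self, wells: dict[str, WellInfo]):
        self.wells = wells

    @classmethod
    def default(cls) -> "PlateLayout":
        wells: dict[str, WellInfo] = {}
        for row in range(1, 11):
            lignin = SCREEN_LIGNIN_LEVELS[(row - 1) // 2]
            for sugar, col in BLANK_COL.items():
                wells[well_id(row, col)] = WellInfo("medium_blank", sugar, lignin)
            wells[well_id(row, WATER_COL)] = WellInfo("water_blank")
            for sugar, cols in GROWTH_COLS.items():
                for col in cols:
                    wells[well_id(row, col)] = WellInfo("growth", sugar, lignin)
        return cls(wells)

    def growth_wells(self):
        return {w: i for w, i in self.wells.items() if i.role == "growth"}

    def blanks_for(self, sugar: str, lignin: float) -> list[str]:
        return [
            w for w, i in self.wells.items()
            if i.role == "medium_blank" and i.sugar_variant == sugar
            and i.lignin_level is not None
            and np.isclose(i.lignin_level, lignin)
        ]

    # -- TOML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for w, i in sorted(self.wells.items()):
            d: dict = {"role": i.role}
            if i.sugar_variant is not None:
                d["sugar"] = i.sugar_variant
            if i.lignin_level is not None:
                d["lignin"] = float(i.lignin_level)
            out[w] = d
        return {"wells": out}

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        wells = {}
        for w, info in d["wells"].items():
            wells[w] = WellInfo(
                info["role"], info.get("sugar"), info.get("lignin")
            )
        return cls(wells)

    def to_toml(self, path) -> None:
        from . import io as _io

        _io.dump_toml(self.to_dict(), path)

    @classmethod
    def from_toml(cls, path) -> "PlateLayout":
        from . import io as _io

        return cls.from_dict(_io.load_toml(path))


@dataclass
class GrowthCurveFit:
    A: float
    mu_max: float
    lam: float
    rss: float
    well: str = ""
    n_points: int = 0
    flags: list[str] = field(default_factory=list)


def blank_correct(od_long: pd.DataFrame, layout: PlateLayout) -> tuple[pd.DataFrame, int]:
    """Subtract the matching medium-blank mean from every growth well.

    ``od_long`` is the long table ``well,t_h,od``; blanks are matched on
    (sugar variant, lignin level) and must share the growth wells' time
    grid. Negative corrected values are floored at 0 and counted; returns
    ``(corrected long frame, n_floored)``.
    """
    by_well = {w: g.sort_values("t_h") for w, g in od_long.groupby("well")}
    out = []
    floored = 0
    for w, info in layout.growth_wells().items():
        if w not in by_well:
            continue
        g = by_well[w]
        blanks = layout.blanks_for(info.sugar_variant, info.lignin_level)
        blanks = [b for b in blanks if b in by_well]
        if not blanks:
            raise ValueError(
                "no medium blank for condition "
                f"(sugar={info.sugar_variant}, lignin={info.lignin_level})"
            )
        t = g["t_h"].to_numpy(float)
        bmat = []
        for b in blanks:
            gb = by_well[b]
            if len(gb) != len(g) or not np.allclose(gb["t_h"].to_numpy(float), t):
                raise ValueError(f"blank well {b} not on the same time grid as {w}")
            bmat.append(gb["od"].to_numpy(float))
        corr = g["od"].to_numpy(float) - np.mean(bmat, axis=0)
        floored += int(np.count_nonzero(corr < 0))
        corr = np.maximum(corr, 0.0)
        out.append(pd.DataFrame({"well": w, "t_h": t, "od": corr}))
    return pd.concat(out, ignore_index=True), floored


def _logistic(t, A, mu, lam, c=0.0):
    z = np.clip(4.0 * mu / A * (lam - t) + 2.0, -500, 500)
    return A / (1.0 + np.exp(z)) + c


def fit_growth_curve(
    times,
    od,
    od_floor: float = 1e-3,
    no_growth_threshold: float = 0.05,
    well: str = "",
    log_input: bool = False,
) -> GrowthCurveFit:
    """Fit the modified logistic to one corrected OD curve.

    The curve is log-transformed as ``y = ln(OD/OD0)`` with OD0 the mean
    of the first two corrected points (floored at ``od_floor``); pass
    ``log_input=True`` when ``od`` already holds log-growth values y.
    Bounded least squares with several starts; returns the best fit. A
    curve whose maximum OD stays below ``no_growth_threshold`` is returned
    as a flagged zero-growth fit (A = 0, mu_max = 0, lam = last time).
    """
    t = np.asarray(times, float)
    od = np.asarray(od, float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points spanning lag and plateau")
    if np.any(~np.isfinite(od)):
        raise ValueError("OD values must be finite")
    if log_input:
        y = od
        if float(np.max(y)) < no_growth_threshold:
            return GrowthCurveFit(
                0.0, 0.0, float(t[-1]), 0.0, well, len(t), ["no growth"]
            )
        w = np.ones_like(y)
    else:
        if float(np.max(od)) < no_growth_threshold:
            return GrowthCurveFit(
                0.0, 0.0, float(t[-1]), 0.0, well, len(t), ["no growth"]
            )
        od0 = max(float(np.mean(od[:2])), od_floor)
        odf = np.maximum(od, od_floor)
        y = np.log(odf / od0)
        # instrument noise is additive in OD, so log-space residuals are
        # weighted ~ OD to keep low-OD points from dominating the fit
        w = np.sqrt(odf / float(np.max(odf)))

    A0 = max(float(np.max(y)), 0.1)
    dy = np.gradient(y, t)
    mu0 = max(float(np.max(dy)), 1e-3)
    above = np.nonzero(y > 0.1 * A0)[0]
    lam0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    t_span = float(t[-1] - t[0])

    def resid(p):
        return w * (_logistic(t, *p) - y)

    # fourth parameter: small log-space baseline offset absorbing the
    # error of the OD0-from-first-two-points estimate
    lo = [1e-6, 1e-6, 0.0, -1.0]
    hi = [5.0 * A0, 20.0 * mu0, float(t[-1]), 1.0]
    starts = [
        (A0, mu0, lam0, 0.0),
        (A0, 0.5 * mu0, max(lam0 - 0.25 * t_span, 0.0), 0.0),
        (1.5 * A0, 2.0 * mu0, min(lam0 + 0.25 * t_span, t[-1]), 0.0),
    ]
    best = None
    for s in starts:
        p0 = np.clip(s, lo, hi)
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(f"logistic fit failed for well {well!r}")
    rss, (A, mu, lam, _c) = best
    return GrowthCurveFit(float(A), float(mu), float(lam), rss, well, len(t))


def beta_from_fit(fit: GrowthCurveFit, definition: str = "mu_max") -> float:
    """Composite growth parameter beta for one fitted well.

    The default is the fitted mu_max; ``A*mu_max`` and ``A`` are also
    available since the composite definition is a convention choice. A
    no-growth fit yields beta = 0 under every definition.
    """
    if definition == "mu_max":
        return fit.mu_max
    if definition == "A*mu_max":
        return fit.A * fit.mu_max
    if definition == "A":
        return fit.A
    raise ValueError(f"unknown beta definition: {definition!r}")


def beta_regression(lignin, beta, exclude=None):
    """OLS of beta on lignin level, with explicit point exclusion.

    Returns a dict with slope, intercept, r2, x_intercept (the
    extrapolated lignin tolerance, -intercept/slope) and flags. Excluded
    points (mask True = drop) take no part in the regression; the
    tolerance is only finite for a negative slope.
    """
    x = np.asarray(lignin, float)
    y = np.asarray(beta, float)
    if exclude is None:
        exclude = np.zeros(len(x), bool)
    exclude = np.asarray(exclude, bool)
    keep = ~exclude
    if keep.sum() < 2 or len(np.unique(x[keep])) < 2:
        raise ValueError("need >= 2 included points with distinct lignin levels")
    slope, intercept = np.polyfit(x[keep], y[keep], 1)
    yhat = slope * x[keep] + intercept
    ss_tot = float(((y[keep] - y[keep].mean()) ** 2).sum())
    ss_res = float(((y[keep] - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flags = []
    if slope < 0:
        x_int = -intercept / slope
    else:
        x_int = float("nan")
        flags.append("no finite tolerance (slope >= 0)")
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(r2),
        "x_intercept": float(x_int),
        "n_used": int(keep.sum()),
        "flags": flags,
    }


def screen_plate(
    od_long: pd.DataFrame,
    layout: PlateLayout,
    beta_definition: str = "mu_max",
) -> dict:
    """End-to-end screening analysis of one plate.

    Blank-corrects, fits every growth well, aggregates the 4 replicate
    wells per (sugar, lignin) condition by median, and regresses beta on
    lignin per sugar variant. Returns per-well fits, the per-condition
    table and the per-sugar regression summaries.
    """
    corrected, floored = blank_correct(od_long, layout)
    fits = []
    growth = layout.growth_wells()
    for w, g in corrected.groupby("well"):
        g = g.sort_values("t_h")
        fit = fit_growth_curve(g["t_h"], g["od"], well=w)
        info = growth[w]
        fits.append(
            {
                "well": w,
                "sugar_variant": info.sugar_variant,
                "lignin_gL": info.lignin_level,
                "A": fit.A,
                "mu_max": fit.mu_max,
                "lam": fit.lam,
                "rss": fit.rss,
                "beta": beta_from_fit(fit, beta_definition),
                "flags": ";".join(fit.flags),
            }
        )
    per_well = pd.DataFrame(fits).sort_values("well").reset_index(drop=True)
    per_condition = (
        per_well.groupby(["sugar_variant", "lignin_gL"], as_index=False)[
            ["A", "mu_max", "lam", "beta"]
        ]
        .median()
        .sort_values(["sugar_variant", "lignin_gL"])
        .reset_index(drop=True)
    )
    regressions = {}
    for sugar, g in per_condition.groupby("sugar_variant"):
        regressions[sugar] = beta_regression(g["lignin_gL"], g["beta"])
    return {
        "per_well": per_well,
        "per_condition": per_condition,
        "regressions": regressions,
        "beta_definition": beta_definition,
        "n_floored": floored,
    }
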