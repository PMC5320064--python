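"""Model-quality statistics: residual sigma, R-squared, one-way ANOVA.

Fit quality of a simulated trajectory against observed data is summarized
by three numbers, computed over all paired state variables pooled into a
single vector:

* ``sigma`` — root-mean-square residual, in concentration units, so runs
  at ~50 g/L scale naturally show larger sigma than ~7 g/L hydrolysate
  runs;
* ``r2`` — coefficient of determination about the observed mean;
* a single-factor ANOVA with two groups (observed values, model values)
  testing, at 95% confidence, the hypothesis that experimental and
  model-derived data are equal: the model is accepted when F < F_critical,
  equivalently p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

POOLED_COLUMNS = ["X_gL", "glc_gL", "xyl_gL", "ara_gL", "la_gL"]


@dataclass
class FitReport:
    sigma: float
    r2: float
    F: float
    F_critical: float
    p: float
    df: tuple[int, int]
    n: int
    equal_at_95: bool
    per_variable_sigma: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _paired(obs, model):
    obs = np.asarray(obs, float)
    model = np.asarray(model, float)
    if obs.shape != model.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {model.shape}")
    mask = ~(np.isnan(obs) | np.isnan(model))
    return obs[mask], model[mask]


def residual_sigma(obs, model) -> float:
    """Root-mean-square deviation sqrt(sum (obs-model)^2 / n), pooled over
    all supplied paired values."""
    o, m = _paired(obs, model)
    if len(o) < 2:
        raise ValueError("need at least 2 paired values")
    return float(np.sqrt(np.mean((o - m) ** 2)))


def r_squared(obs, model) -> float:
    """1 - SS_res/SS_tot with SS_tot about the observed mean."""
    o, m = _paired(obs, model)
    if len(o) < 3:
        raise ValueError("need at least 3 paired values")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(((o - m) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def anova_obs_vs_model(obs, model, alpha: float = 0.05):
    """One-way ANOVA with two groups: observed vs model values.

    Degrees of freedom are (1, 2n-2); F_critical is the upper-alpha
    quantile of the F distribution at those df. Returns
    ``(F, F_critical, p, (df1, df2), flags)``.
    """
    o, m = _paired(obs, model)
    n = len(o)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    df1, df2 = 1, 2 * n - 2
    f_crit = float(stats.f.ppf(1.0 - alpha, df1, df2))
    flags: list[str] = []
    ss_within = float(((o - o.mean()) ** 2).sum() + ((m - m.mean()) ** 2).sum())
    ss_between = n * ((o.mean() - (o.mean() + m.mean()) / 2) ** 2
                      + (m.mean() - (o.mean() + m.mean()) / 2) ** 2)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, f_crit, 1.0, (df1, df2), flags
        flags.append("zero within-group variance with nonzero group difference")
        return float("inf"), f_crit, 0.0, (df1, df2), flags
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), f_crit, p, (df1, df2), flags


def evaluate_fit(
    observed: pd.DataFrame,
    model: pd.DataFrame,
    columns=None,
    alpha: float = 0.05,
) -> FitReport:
    """Pooled FitReport for an observed series vs a simulated trajectory.

    Both frames must share the time grid; all state-variable columns are
    pooled into the two ANOVA groups (one F per fermentation), with a
    per-variable sigma breakdown retained for diagnosis.
    """
    if columns is None:
        columns = [c for c in POOLED_COLUMNS if c in observed and c in model]
    if not np.allclose(
        observed["t_h"].to_numpy(float), model["t_h"].to_numpy(float)
    ):
        raise ValueError("observed and model series must share the time grid")
    obs_pool, mod_pool = [], []
    per_var = {}
    for c in columns:
        o, m = _paired(observed[c], model[c])
        if len(o) >= 2:
            per_var[c] = float(np.sqrt(np.mean((o - m) ** 2)))
        obs_pool.append(o)
        mod_pool.append(m)
    o = np.concatenate(obs_pool)
    m = np.concatenate(mod_pool)
    sigma = residual_sigma(o, m)
    r2 = r_squared(o, m)
    F, f_crit, p, df, flags = anova_obs_vs_model(o, m, alpha)
    return FitReport(
        sigma=sigma, r2=r2, F=F, F_critical=f_crit, p=p, df=df, n=len(o),
        equal_at_95=bool(F < f_crit), per_variable_sigma=per_var, flags=flags,
    )
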