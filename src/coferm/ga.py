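"""Genetic-algorithm least-squares estimation of kinetic parameters.

Fits the cofermentation model to an observed time series by minimizing a
weighted sum of squared residuals over all state variables. The optimizer
is a bounded real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation clipped to the bounds, elitism), fully
reproducible from a single seed. An optional derivative-free simplex
polish can refine the GA winner; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    FermentState,
    MonodParams,
    SimulationError,
    simulate,
)

#: observed-series column -> short variable key used in weights
SERIES_VARS = {"X_gL": "X", "glc_gL": "glc", "xyl_gL": "xyl", "ara_gL": "ara", "la_gL": "la"}


@dataclass
class GAConfig:
    """Hyperparameters and per-parameter (low, high) bounds.

    Defaults are sized for bounded problems of up to ~15 dimensions.
    """

    bounds: dict[str, tuple[float, float]]
    population_size: int = 80
    generations: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1
    elite_count: int = 2
    tournament_size: int = 3
    seed: int = 0
    polish: bool = False

    def __post_init__(self) -> None:
        if self.population_size < self.elite_count + 2:
            raise ValueError("population_size must be >= elite_count + 2")
        if not self.bounds:
            raise ValueError("bounds must name at least one free parameter")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy low < high")
        for p in ("crossover_prob", "mutation_prob"):
            v = getattr(self, p)
            if not 0 <= v <= 1:
                raise ValueError(f"{p} must lie in [0, 1]")


@dataclass
class FitResult:
    best_params: dict[str, float]
    best_sse: float
    history: list[float]
    evaluations: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.history)
        if len(h) and np.any(np.diff(h) > 0):
            raise ValueError("GA history must be non-increasing (elitism)")
        if len(h) and h[-1] != self.best_sse:
            raise ValueError("best_sse must equal the final history entry")


def default_weights(observed: pd.DataFrame) -> dict[str, float]:
    """Per-variable weights 1/range^2, so ~5 g/L biomass and ~65 g/L
    lactate contribute comparably to the pooled objective."""
    w = {}
    for col, key in SERIES_VARS.items():
        if col not in observed:
            continue
        vals = observed[col].dropna()
        if len(vals) < 2:
            continue
        rng = float(vals.max() - vals.min())
        w[key] = 1.0 / max(rng, 1e-9) ** 2
    return w


def sse_objective(
    observed: pd.DataFrame,
    params: MonodParams,
    weights: dict[str, float] | None = None,
    init: FermentState | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Weighted sum of squared residuals between data and simulation.

    The model is simulated on the observed time grid; missing observations
    (NaN cells) are skipped. A failed simulation returns +inf so the GA
    treats the parameter vector as infeasible.
    """
    if len(observed) < 2:
        raise ValueError("observed series needs at least 2 time points")
    if weights is None:
        weights = default_weights(observed)
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    if init is None:
        init = _init_from_series(observed)
    t = observed["t_h"].to_numpy(float)
    try:
        traj = simulate(params, init, t, rtol=rtol, atol=atol)
    except (SimulationError, ValueError):
        return float("inf")
    total = 0.0
    for col, key in SERIES_VARS.items():
        w = weights.get(key, 0.0)
        if w == 0.0 or col not in observed:
            continue
        obs = observed[col].to_numpy(float)
        mod = traj.data[col].to_numpy(float)
        mask = ~np.isnan(obs)
        total += w * float(((obs[mask] - mod[mask]) ** 2).sum())
    return total


def _init_from_series(observed: pd.DataFrame) -> FermentState:
    row = observed.iloc[0]

    def val(col):
        v = row.get(col, 0.0)
        return 0.0 if pd.isna(v) else float(v)

    return FermentState(
        float(row["t_h"]), val("X_gL"), val("glc_gL"), val("xyl_gL"),
        val("ara_gL"), val("la_gL"), val("lignin_gL"),
    )


def ga_minimize(objective, config: GAConfig) -> FitResult:
    """Minimize ``objective(param_dict) -> float`` within the bounds.

    Deterministic for a fixed seed: same seed and config give a
    bit-identical FitResult.
    """
    names = list(config.bounds)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    P, D = config.population_size, len(names)

    def f(x: np.ndarray) -> float:
        return float(objective(dict(zip(names, x.tolist()))))

    pop = lo + rng.random((P, D)) * span
    fitness = np.array([f(x) for x in pop])
    evaluations = P
    history: list[float] = [float(np.min(fitness))]

    def tournament() -> int:
        idx = rng.integers(0, P, size=config.tournament_size)
        return idx[np.argmin(fitness[idx])]

    for _ in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elite_count]]
        while len(new_pop) < P:
            a, b = pop[tournament()], pop[tournament()]
            if rng.random() < config.crossover_prob:
                # blend (BLX-0.5) crossover
                cmin, cmax = np.minimum(a, b), np.maximum(a, b)
                d = cmax - cmin
                child = cmin - 0.5 * d + rng.random(D) * 2.0 * d
            else:
                child = a.copy()
            mut = rng.random(D) < config.mutation_prob
            child = child + mut * rng.normal(0.0, config.mutation_scale * span)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop[:P])
        # elites keep their fitness; only offspring are re-evaluated
        fit_new = fitness[order[: config.elite_count]].tolist()
        for x in pop[config.elite_count:]:
            fit_new.append(f(x))
            evaluations += 1
        fitness = np.array(fit_new)
        history.append(float(np.min(fitness)))

    best_i = int(np.argmin(fitness))
    best_x, best_f = pop[best_i].copy(), float(fitness[best_i])

    if config.polish:
        res = minimize(
            f, best_x, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": 200 * D, "xatol": 1e-8, "fatol": 1e-10},
        )
        evaluations += res.nfev
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
            history.append(best_f)

    cfg = asdict(config)
    cfg["bounds"] = {k: list(v) for k, v in config.bounds.items()}
    return FitResult(
        best_params=dict(zip(names, best_x.tolist())),
        best_sse=best_f,
        history=history,
        evaluations=evaluations,
        seed=config.seed,
        config=cfg,
    )


def fit_series(
    observed: pd.DataFrame,
    base_params: MonodParams,
    config: GAConfig,
    weights: dict[str, float] | None = None,
    init: FermentState | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[MonodParams, FitResult]:
    """Fit the parameters named in ``config.bounds``; all others stay at
    ``base_params``. Returns the fitted parameter set and the FitResult."""
    if weights is None:
        weights = default_weights(observed)

    def objective(free: dict[str, float]) -> float:
        try:
            p = base_params.replace(**free)
        except ValueError:
            return float("inf")
        return sse_objective(observed, p, weights, init, rtol, atol)

    result = ga_minimize(objective, config)
    fitted = base_params.replace(**result.best_params)
    return fitted, result
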