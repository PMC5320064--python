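"""Independent oracles used by the test suite.

Everything here is deliberately naive (fixed-step integration, plain
Python loops, closed-form normal equations) and shares no code with the
production paths it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

from coferm.model import FermentState, MonodParams


def naive_rates(y, p: MonodParams):
    """Per-sugar rates recomputed with scalar arithmetic."""
    X, sg, sx, sa, P, L = [max(v, 0.0) for v in y]
    mus = []
    for mu_max, K_S, S in (
        (p.mu_max_glc, p.K_S_glc, sg),
        (p.mu_max_xyl, p.K_S_xyl, sx),
        (p.mu_max_ara, p.K_S_ara, sa),
    ):
        mu = mu_max * S / (K_S + S)
        mus.append(mu)
    if p.use_repression:
        rep = p.K_rep / (p.K_rep + sg)
        mus[1] *= rep
        mus[2] *= rep
    fac = 1.0
    if p.use_lignin_inhibition:
        fac /= 1.0 + L / p.K_L
    if p.use_product_inhibition:
        fac *= max(0.0, 1.0 - P / p.P_max) ** p.n_P
    return [m * fac for m in mus]


def _deriv(y, p: MonodParams):
    mus = naive_rates(y, p)
    X = max(y[0], 0.0)
    yields = (p.Y_XS_glc, p.Y_XS_xyl, p.Y_XS_ara)
    alphas = (p.alpha_glc, p.alpha_xyl, p.alpha_ara)
    dX = sum(mus) * X
    dS = [-m / yy * X for m, yy in zip(mus, yields)]
    dP = sum(a * m for a, m in zip(alphas, mus)) * X + p.beta_LP * X
    return np.array([dX, dS[0], dS[1], dS[2], dP, 0.0])


def rk4_simulate(p: MonodParams, init: FermentState, t_grid, dt: float = 1e-3):
    """Fixed-step classical RK4; returns states at the grid times."""
    t_grid = np.asarray(t_grid, float)
    y = init.as_array()
    out = [y.copy()]
    t = t_grid[0]
    for t_next in t_grid[1:]:
        n = max(int(math.ceil((t_next - t) / dt)), 1)
        h = (t_next - t) / n
        for _ in range(n):
            k1 = _deriv(y, p)
            k2 = _deriv(y + 0.5 * h * k1, p)
            k3 = _deriv(y + 0.5 * h * k2, p)
            k4 = _deriv(y + h * k3, p)
            y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        out.append(y.copy())
        t = t_next
    return np.array(out)


def euler_simulate(p: MonodParams, init: FermentState, t_grid, dt: float = 1e-3):
    """Forward-Euler brute force; the crudest possible cross-check."""
    t_grid = np.asarray(t_grid, float)
    y = init.as_array()
    out = [y.copy()]
    t = t_grid[0]
    for t_next in t_grid[1:]:
        n = max(int(math.ceil((t_next - t) / dt)), 1)
        h = (t_next - t) / n
        for _ in range(n):
            y = y + h * _deriv(y, p)
        y = np.maximum(y, 0.0)
        out.append(y.copy())
        t = t_next
    return np.array(out)


def naive_sigma(obs, model) -> float:
    s, n = 0.0, 0
    for o, m in zip(obs, model):
        s += (o - m) ** 2
        n += 1
    return math.sqrt(s / n)


def naive_r2(obs, model) -> float:
    mean = sum(obs) / len(obs)
    ss_tot = sum((o - mean) ** 2 for o in obs)
    ss_res = sum((o - m) ** 2 for o, m in zip(obs, model))
    return 1.0 - ss_res / ss_tot


def ols_normal_equations(x, y):
    """Closed-form simple-regression slope/intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
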