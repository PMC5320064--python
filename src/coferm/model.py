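"""Unstructured Monod-kinetics model of triple-sugar cofermentation.

The model describes anaerobic growth of *Bacillus coagulans* on a glucose /
xylose / arabinose mixture with lactic acid as the (essentially sole)
product, in the presence of a fixed level of alkali-lignin acting as a
non-consumed inhibitor.

State variables (all g/L, time in h):

    X      biomass
    S_glc, S_xyl, S_ara   sugars
    P_la   lactate
    L      alkali-lignin (constant over a run)

Per-sugar specific growth rates follow Monod saturation, multiplied by
three optional inhibition factors:

    mu_i = mu_max_i * S_i/(K_S_i + S_i) * rep_i(S_glc)
           * 1/(1 + L/K_L) * max(0, 1 - P_la/P_max)**n_P

where ``rep_glc = 1`` and ``rep_xyl = rep_ara = K_rep/(K_rep + S_glc)`` is a
smooth catabolite-repression term (glucose suppresses pentose uptake
without a hard diauxic switch, so partial simultaneous consumption is
possible). Lactate formation is Luedeking-Piret: a growth-associated term
per sugar plus a non-growth-associated term.

    dX/dt   = mu * X          with mu = sum_i mu_i
    dS_i/dt = -(mu_i / Y_XS_i) * X
    dP/dt   = (sum_i alpha_i * mu_i) * X + beta_LP * X
    dL/dt   = 0
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd
from scipy.integrate import odeint

SUGARS = ("glc", "xyl", "ara")

#: canonical column order for trajectory / observed-series CSV files
SERIES_COLUMNS = ["t_h", "X_gL", "glc_gL", "xyl_gL", "ara_gL", "la_gL", "lignin_gL"]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8


class SimulationError(RuntimeError):
    """Integrator failure; carries the last good state if available."""

    def __init__(self, message: str, last_state: "FermentState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class FermentState:
    """Snapshot of a fermentation: time plus all concentrations (g/L)."""

    t: float
    X: float
    S_glc: float
    S_xyl: float
    S_ara: float
    P_la: float
    L: float = 0.0

    def validate(self) -> None:
        vals = [self.t, self.X, self.S_glc, self.S_xyl, self.S_ara, self.P_la, self.L]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite fermentation state: {self}")
        conc = vals[1:]
        if any(v < 0 for v in conc):
            raise ValueError(f"negative concentration in state: {self}")

    def as_array(self) -> np.ndarray:
        """State vector [X, S_glc, S_xyl, S_ara, P_la, L] (time excluded)."""
        return np.array(
            [self.X, self.S_glc, self.S_xyl, self.S_ara, self.P_la, self.L], float
        )

    @classmethod
    def from_array(cls, t: float, y: np.ndarray) -> "FermentState":
        return cls(t, *(float(v) for v in y))


@dataclass
class MonodParams:
    """Kinetic constants of the cofermentation model.

    Units: mu_max_* 1/h; K_S_*, K_rep, K_L, P_max g/L; Y_XS_* g biomass per
    g sugar; alpha_* g lactate per g biomass; beta_LP g lactate per g
    biomass per h; n_P dimensionless.

    Each inhibition term can be switched off independently
    (``use_repression``, ``use_lignin_inhibition``,
    ``use_product_inhibition``) so alternative rate-law variants can be
    compared without editing the model.
    """

    mu_max_glc: float
    mu_max_xyl: float
    mu_max_ara: float
    K_S_glc: float
    K_S_xyl: float
    K_S_ara: float
    Y_XS_glc: float
    Y_XS_xyl: float
    Y_XS_ara: float
    K_rep: float = 1.0
    K_L: float = 2.0
    P_max: float = 90.0
    n_P: float = 1.0
    alpha_glc: float = 0.0
    alpha_xyl: float = 0.0
    alpha_ara: float = 0.0
    beta_LP: float = 0.0
    use_repression: bool = True
    use_lignin_inhibition: bool = True
    use_product_inhibition: bool = True

    def __post_init__(self) -> None:
        for name in (
            "mu_max_glc", "mu_max_xyl", "mu_max_ara",
            "K_S_glc", "K_S_xyl", "K_S_ara",
            "K_rep", "K_L", "P_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("Y_XS_glc", "Y_XS_xyl", "Y_XS_ara"):
            y = getattr(self, name)
            if not (0 < y <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {y}")
        if self.n_P < 0:
            raise ValueError(f"n_P must be >= 0, got {self.n_P}")
        for name in ("alpha_glc", "alpha_xyl", "alpha_ara", "beta_LP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- flat-table serialization (lossless round trip) ------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MonodParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "MonodParams":
        d = self.to_dict()
        d.update(kw)
        return MonodParams.from_dict(d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MonodParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_toml(self, path) -> None:
        from . import io as _io

        _io.dump_toml(self.to_dict(), path)

    @classmethod
    def from_toml(cls, path) -> "MonodParams":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


@dataclass
class Trajectory:
    """Simulated or observed time course on a stated grid.

    ``data`` uses the canonical CSV schema (SERIES_COLUMNS). ``clip_events``
    counts integrator states that were floored at zero.
    """

    data: pd.DataFrame
    provenance: str = "simulated"
    clip_events: int = 0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        t = self.data["t_h"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def state_at(self, idx: int) -> FermentState:
        row = self.data.iloc[idx]
        return FermentState(
            row.t_h, row.X_gL, row.glc_gL, row.xyl_gL, row.ara_gL,
            row.la_gL, row.lignin_gL,
        )


def specific_rates(state: FermentState, params: MonodParams):
    """Per-sugar specific growth rates and their sum.

    Returns ``(mu_by_sugar, mu_total)`` where ``mu_by_sugar`` maps
    'glc'/'xyl'/'ara' to the rate contribution (1/h). All rates are
    non-negative; zero substrate gives zero rate.
    """
    state.validate()
    y = state.as_array()
    mu = _rates_from_vector(y, params)
    return dict(zip(SUGARS, mu)), float(mu.sum())


def _rates_from_vector(y: np.ndarray, p: MonodParams) -> np.ndarray:
    """mu_i from a (clipped) state vector; the hot path shared with the RHS."""
    s = np.maximum(y[1:4], 0.0)
    L = max(y[5], 0.0)
    P = max(y[4], 0.0)

    mu_max = np.array([p.mu_max_glc, p.mu_max_xyl, p.mu_max_ara])
    K_S = np.array([p.K_S_glc, p.K_S_xyl, p.K_S_ara])
    mu = mu_max * s / (K_S + s)

    if p.use_repression:
        rep = p.K_rep / (p.K_rep + s[0])
        mu[1] *= rep
        mu[2] *= rep
    if p.use_lignin_inhibition:
        mu *= 1.0 / (1.0 + L / p.K_L)
    if p.use_product_inhibition:
        mu *= max(0.0, 1.0 - P / p.P_max) ** p.n_P
    return mu


def _make_rhs(p: MonodParams):
    """Scalar-math RHS closure; the integrator hot path.

    Concentrations are clipped at zero inside the rate evaluation, so a
    slightly negative overshoot (≈ atol) cannot drive spurious fluxes.
    """
    mg, mx, ma = p.mu_max_glc, p.mu_max_xyl, p.mu_max_ara
    kg, kx, ka = p.K_S_glc, p.K_S_xyl, p.K_S_ara
    yg, yx, ya = p.Y_XS_glc, p.Y_XS_xyl, p.Y_XS_ara
    ag, ax, aa = p.alpha_glc, p.alpha_xyl, p.alpha_ara
    krep, kl, pmax, npow, blp = p.K_rep, p.K_L, p.P_max, p.n_P, p.beta_LP
    use_rep, use_lig, use_prod = (
        p.use_repression, p.use_lignin_inhibition, p.use_product_inhibition
    )

    def rhs(y, t):
        X = y[0] if y[0] > 0 else 0.0
        sg = y[1] if y[1] > 0 else 0.0
        sx = y[2] if y[2] > 0 else 0.0
        sa = y[3] if y[3] > 0 else 0.0
        P = y[4] if y[4] > 0 else 0.0
        L = y[5] if y[5] > 0 else 0.0
        mug = mg * sg / (kg + sg)
        mux = mx * sx / (kx + sx)
        mua = ma * sa / (ka + sa)
        if use_rep:
            rep = krep / (krep + sg)
            mux *= rep
            mua *= rep
        fac = 1.0
        if use_lig:
            fac /= 1.0 + L / kl
        if use_prod:
            r = 1.0 - P / pmax
            fac *= (r if r > 0 else 0.0) ** npow
        mug *= fac
        mux *= fac
        mua *= fac
        return (
            (mug + mux + mua) * X,
            -mug / yg * X,
            -mux / yx * X,
            -mua / ya * X,
            (ag * mug + ax * mux + aa * mua) * X + blp * X,
            0.0,
        )

    return rhs


def simulate(
    params: MonodParams,
    init: FermentState,
    t_grid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the cofermentation ODEs on ``t_grid``.

    The grid must start at ``init.t``. Concentrations are clipped at zero
    (stiff end-of-substrate dynamics can overshoot by ~atol); each clipped
    value is counted in ``Trajectory.clip_events``. Deterministic for fixed
    inputs and tolerances.
    """
    init.validate()
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if not np.isclose(t_grid[0], init.t):
        raise ValueError(f"t_grid must start at init.t={init.t}, got {t_grid[0]}")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    if len(t_grid) == 1:
        ys = init.as_array()[None, :]
    else:
        ys, info = odeint(
            _make_rhs(params),
            init.as_array(),
            t_grid,
            rtol=rtol,
            atol=atol,
            full_output=True,
            printmessg=False,
        )
        if info["message"] != "Integration successful.":
            n_ok = int(np.max(np.nonzero(np.isfinite(ys).all(axis=1))[0], initial=0))
            last = FermentState.from_array(t_grid[n_ok], ys[n_ok])
            raise SimulationError(f"integration failed: {info['message']}", last)

    clip_events = int(np.count_nonzero(ys < 0))
    ys = np.maximum(ys, 0.0)
    df = pd.DataFrame(
        np.column_stack([t_grid, ys]), columns=SERIES_COLUMNS
    )
    return Trajectory(df, "simulated", clip_events, rtol, atol)


def fermentation_time(
    traj: Trajectory, threshold: float = 0.5, rule: str = "sugar_depletion"
) -> float:
    """Fermentation duration FT (h).

    ``sugar_depletion`` (default): first grid time at which the total
    residual sugar drops below ``threshold`` g/L, else the last grid time.
    ``harvest``: simply the last grid time (fixed harvest convention; some
    runs are stopped at a set time with sugars left over).
    """
    df = traj.data
    if len(df) == 0:
        raise ValueError("empty trajectory")
    if rule == "harvest":
        return float(df["t_h"].iloc[-1])
    if rule != "sugar_depletion":
        raise ValueError(f"unknown stop rule: {rule!r}")
    total = df[["glc_gL", "xyl_gL", "ara_gL"]].sum(axis=1).to_numpy()
    below = np.nonzero(total < threshold)[0]
    if len(below):
        return float(df["t_h"].iloc[below[0]])
    return float(df["t_h"].iloc[-1])
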