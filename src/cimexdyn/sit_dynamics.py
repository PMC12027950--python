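"""Susceptible–Infested–Treated (SIT) household infestation dynamics.

Houses in a community of fixed size ``N`` move between three stocks:
susceptible (S), infested (I) and treated (T).  Infestation spreads by
frequency-dependent contact at rate ``beta``, resolves spontaneously at
rate ``gamma`` (I -> S), is treated at uptake rate ``tau`` (I -> T), and
treated houses become susceptible again once control wears off, at rate
``alpha`` (T -> S).  All rates are per month.

The two-species extension couples two such systems over the same houses:
a house infested by one bed-bug species makes its neighbourhood more
susceptible to the other, modelled as a multiplicative amplification of
the force of infestation, ``(beta_k/N) * I_k * (1 + kappa_k * I_j / N)``.
Setting both coupling coefficients to zero recovers two independent
single-species systems exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SITParameters",
    "SITState",
    "Trajectory",
    "TwoSpeciesParameters",
    "sit_derivatives",
    "basic_reproduction_number",
    "endemic_equilibrium",
    "simulate_sit",
    "simulate_two_species",
]

# Integration accuracy.  Tight, high-order integration keeps the global
# error well below 1e-9*N so that algebraically equivalent runs (e.g. a
# decoupled two-species system vs. two single-species runs) agree to that
# level despite different adaptive step sequences.
_METHOD = "DOP853"
_RTOL = 1e-11
_ATOL_SCALE = 1e-11  # absolute tolerance = _ATOL_SCALE * N

DEFAULT_DT = 0.1  # months
DEFAULT_HORIZON = 24.0  # months
DEFAULT_KAPPA = 0.25


@dataclass(frozen=True)
class SITParameters:
    """Rate constants of one species' infestation model (per month).

    ``beta > 0``: transmission; ``gamma > 0``: spontaneous recovery
    (I -> S); ``tau > 0``: treatment uptake (I -> T); ``alpha >= 0``:
    post-treatment return (T -> S).
    """

    beta: float
    gamma: float
    tau: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "tau", "alpha"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class SITState:
    """Stocks of houses at one instant: susceptible, infested, treated."""

    s: float
    i: float
    t: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s", "i", "t"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"stock {name} must be finite and >= 0, got {v!r}")

    @property
    def n(self) -> float:
        """Total houses S + I + T."""
        return self.s + self.i + self.t

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.i, self.t], dtype=float)


@dataclass(frozen=True)
class TwoSpeciesParameters:
    """Parameters of the coupled two-species system.

    ``kappa_ab`` amplifies species-a transmission per unit prevalence of
    species b (and ``kappa_ba`` symmetrically).  Zero coupling reduces the
    system to two independent single-species models.
    """

    species_a: SITParameters
    species_b: SITParameters
    kappa_ab: float = DEFAULT_KAPPA
    kappa_ba: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.kappa_ab < 0 or self.kappa_ba < 0:
            raise ValueError("coupling coefficients must be >= 0")


@dataclass
class Trajectory:
    """Time grid plus stocks for one or two species.

    ``states`` has shape ``(n_times, 3)`` for a single species or
    ``(n_times, n_species, 3)`` for paired dynamics; the last axis is
    (S, I, T).  Latent stocks of an observation-only series may be NaN.
    """

    times: np.ndarray
    states: np.ndarray
    n_total: float
    species: tuple[str, ...] = ("a",)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_species(self) -> int:
        return 1 if self.states.ndim == 2 else self.states.shape[1]

    def stocks(self, species: int = 0) -> np.ndarray:
        """(n_times, 3) array of (S, I, T) for one species."""
        return self.states if self.states.ndim == 2 else self.states[:, species, :]

    def infested(self, species: int = 0) -> np.ndarray:
        return self.stocks(species)[:, 1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns time, species, S, I, T."""
        rows = []
        for k, label in enumerate(self.species):
            st = self.stocks(k)
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "species": label,
                        "S": st[:, 0],
                        "I": st[:, 1],
                        "T": st[:, 2],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_total: float | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        labels = tuple(dict.fromkeys(df["species"].astype(str)))
        times = np.array(sorted(df["time"].unique()), dtype=float)
        states = np.full((len(times), len(labels), 3), np.nan)
        for k, label in enumerate(labels):
            sub = df[df["species"].astype(str) == label].sort_values("time")
            states[:, k, :] = sub[["S", "I", "T"]].to_numpy()
        if len(labels) == 1:
            states = states[:, 0, :]
        if n_total is None:
            n_total = float(np.nansum(states[0]) / max(len(labels), 1))
        return cls(times=times, states=states, n_total=n_total, species=labels)


def sit_derivatives(
    state: SITState, params: SITParameters, n_total: float
) -> tuple[float, float, float]:
    """Right-hand side (dS/dt, dI/dt, dT/dt) of the single-species system.

    dS/dt = -(beta/N) S I + gamma I + alpha T
    dI/dt =  (beta/N) S I - (gamma + tau) I
    dT/dt =  tau I - alpha T

    The three components sum to zero exactly (houses are conserved).
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be > 0, got {n_total}")
    foi = params.beta / n_total * state.s * state.i  # force of infestation * S
    ds = -foi + params.gamma * state.i + params.alpha * state.t
    di = foi - (params.gamma + params.tau) * state.i
    dt = params.tau * state.i - params.alpha * state.t
    return ds, di, dt


def basic_reproduction_number(params: SITParameters) -> float:
    """R0 = beta / (gamma + tau); infestation persists iff R0 > 1."""
    return params.beta / (params.gamma + params.tau)


def endemic_equilibrium(params: SITParameters, n_total: float) -> SITState | None:
    """Positive steady state of the SIT system, or ``None`` if absent.

    For R0 > 1 and alpha > 0:
        S* = N (gamma + tau) / beta
        I* = (N - S*) / (1 + tau/alpha)
        T* = tau I* / alpha
    When alpha = 0 the treated class absorbs every house that ever seeks
    treatment, so no positive endemic state exists and ``None`` is
    returned.  Below threshold (R0 <= 1) the only equilibrium is
    infestation-free, also reported as ``None``.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be > 0, got {n_total}")
    if basic_reproduction_number(params) <= 1 or params.alpha == 0:
        return None
    s_star = n_total * (params.gamma + params.tau) / params.beta
    i_star = (n_total - s_star) / (1.0 + params.tau / params.alpha)
    t_star = params.tau * i_star / params.alpha
    return SITState(s=s_star, i=i_star, t=t_star, time=math.inf)


def _check_init(init: SITState, n_total: float) -> None:
    if abs(init.n - n_total) > 1e-9 * n_total:
        raise ValueError(
            f"initial stocks sum to {init.n}, expected N={n_total} (within 1e-9*N)"
        )


def _grid(t0: float, horizon: float, dt: float) -> np.ndarray:
    if horizon <= 0 or dt <= 0:
        raise ValueError("horizon and dt must be > 0")
    n_steps = int(round(horizon / dt))
    grid = t0 + dt * np.arange(n_steps + 1)
    if grid[-1] < t0 + horizon - 1e-12:
        grid = np.append(grid, t0 + horizon)
    return grid


def simulate_sit(
    params: SITParameters,
    init: SITState,
    horizon: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Integrate the single-species system on a uniform output grid.

    Conservation |S+I+T-N| stays below 1e-6*N at every output time.
    """
    n_total = init.n
    if n_total <= 0:
        raise ValueError("initial population must be positive")
    grid = _grid(init.time, horizon, dt)

    b, g, tau, a = params.beta, params.gamma, params.tau, params.alpha

    def rhs(_t, y):
        s, i, t = y
        foi = b / n_total * s * i
        return (-foi + g * i + a * t, foi - (g + tau) * i, tau * i - a * t)

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        init.as_array(),
        method=_METHOD,
        t_eval=grid,
        rtol=_RTOL,
        atol=_ATOL_SCALE * n_total,
    )
    if not sol.success:  # pragma: no cover - DOP853 on this smooth system
        raise RuntimeError(f"integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, n_total=n_total)


def simulate_two_species(
    params: TwoSpeciesParameters,
    init_a: SITState,
    init_b: SITState,
    n_total: float | None = None,
    horizon: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Integrate the coupled two-species system over the same N houses.

    Each species follows the single-species equations with its force of
    infestation amplified by the other species' prevalence:
    ``(beta_k/N) * S_k * I_k * (1 + kappa_k * I_j / N)``.
    """
    if n_total is None:
        n_total = init_a.n
    if abs(init_a.n - n_total) > 1e-9 * n_total or abs(init_b.n - n_total) > 1e-9 * n_total:
        raise ValueError("both species must share the same total population N")
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    grid = _grid(min(init_a.time, init_b.time), horizon, dt)

    pa, pb = params.species_a, params.species_b
    kab, kba = params.kappa_ab, params.kappa_ba

    def rhs(_t, y):
        sa, ia, ta, sb, ib, tb = y
        foi_a = pa.beta / n_total * sa * ia * (1.0 + kab * ib / n_total)
        foi_b = pb.beta / n_total * sb * ib * (1.0 + kba * ia / n_total)
        return (
            -foi_a + pa.gamma * ia + pa.alpha * ta,
            foi_a - (pa.gamma + pa.tau) * ia,
            pa.tau * ia - pa.alpha * ta,
            -foi_b + pb.gamma * ib + pb.alpha * tb,
            foi_b - (pb.gamma + pb.tau) * ib,
            pb.tau * ib - pb.alpha * tb,
        )

    y0 = np.concatenate([init_a.as_array(), init_b.as_array()])
    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        method=_METHOD,
        t_eval=grid,
        rtol=_RTOL,
        atol=_ATOL_SCALE * n_total,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T.reshape(len(sol.t), 2, 3)
    return Trajectory(times=sol.t, states=states, n_total=n_total, species=("a", "b"))
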