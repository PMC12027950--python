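"""Deriving and recovering SIT rate constants.

Two routes to parameters:

* :func:`params_from_survey` maps per-county survey aggregates (prevalence,
  control uptake, mean durations) to rates via reciprocal durations and an
  inversion of the closed-form endemic equilibrium.
* :func:`fit_sit` recovers rates from an observed (possibly noisy)
  infested-house time series by least squares on log-parameters, with any
  subset of parameters held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .sit_dynamics import (
    SITParameters,
    SITState,
    Trajectory,
    basic_reproduction_number,
    simulate_sit,
)

__all__ = ["SurveySummary", "FitResult", "params_from_survey", "fit_sit"]

_PARAM_NAMES = ("beta", "gamma", "tau", "alpha")


@dataclass(frozen=True)
class SurveySummary:
    """Per-county aggregates from a household survey.

    Fractions are in [0, 1]; durations are months > 0.  ``treat_fraction``
    is the fraction of infested households applying control per month and
    maps directly onto the uptake rate tau.
    """

    county_label: str
    n_respondents: int
    prevalence_a: float
    prevalence_b: float
    treat_fraction: float
    effectiveness_months: float
    self_recovery_months: float

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be > 0")
        for name in ("prevalence_a", "prevalence_b", "treat_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effectiveness_months", "self_recovery_months"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a positive duration, got {v}")

    @staticmethod
    def table_to_csv(summaries: list["SurveySummary"], path) -> None:
        # %.17g keeps the round trip lossless for float64 fields
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            path, index=False, float_format="%.17g"
        )

    @staticmethod
    def table_from_csv(path) -> list["SurveySummary"]:
        df = pd.read_csv(path, float_precision="round_trip")
        return [
            SurveySummary(
                county_label=str(r.county_label),
                n_respondents=int(r.n_respondents),
                prevalence_a=float(r.prevalence_a),
                prevalence_b=float(r.prevalence_b),
                treat_fraction=float(r.treat_fraction),
                effectiveness_months=float(r.effectiveness_months),
                self_recovery_months=float(r.self_recovery_months),
            )
            for r in df.itertuples()
        ]


@dataclass
class FitResult:
    params: SITParameters
    residual_norm: float
    converged: bool
    n_iter: int
    objective_history: list[float] = field(default_factory=list)


def params_from_survey(
    summary: SurveySummary,
    species: str = "a",
    beta_calibration: str = "equilibrium",
) -> SITParameters:
    """Derive one species' SITParameters from survey aggregates.

    alpha = 1/effectiveness_months, gamma = 1/self_recovery_months,
    tau = treat_fraction per month.  beta is calibrated so the endemic
    prevalence I*/N equals the surveyed prevalence (inverting the
    closed-form equilibrium); zero prevalence falls back to the
    below-threshold default R0 = 0.5.
    """
    if species not in ("a", "b"):
        raise ValueError(f"species must be 'a' or 'b', got {species!r}")
    if beta_calibration != "equilibrium":
        raise ValueError(f"unknown beta_calibration mode {beta_calibration!r}")
    alpha = 1.0 / summary.effectiveness_months
    gamma = 1.0 / summary.self_recovery_months
    tau = summary.treat_fraction
    if tau <= 0:
        raise ValueError("treat_fraction must be > 0 to define an uptake rate")
    prevalence = summary.prevalence_a if species == "a" else summary.prevalence_b
    if prevalence == 0:
        beta = 0.5 * (gamma + tau)  # R0 = 0.5 below-threshold default
    else:
        # I* = p N, S* = N - I*(1 + tau/alpha); beta = N(gamma+tau)/S*.
        s_frac = 1.0 - prevalence * (1.0 + tau / alpha)
        if s_frac <= 0:
            raise ValueError(
                f"prevalence {prevalence} with tau/alpha={tau / alpha:.3g} implies "
                "a non-positive susceptible stock; survey summary is inconsistent"
            )
        beta = (gamma + tau) / s_frac
    return SITParameters(beta=beta, gamma=gamma, tau=tau, alpha=alpha)


def _observed_series(observed: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    times = observed.times
    i_obs = observed.infested()
    if len(times) < 8:
        raise ValueError(f"need >= 8 observation times, got {len(times)}")
    if not np.all(np.isfinite(i_obs)):
        raise ValueError("observed infested series contains non-finite values")
    return times, i_obs


def fit_sit(
    observed: Trajectory,
    n_total: float,
    init_guess: SITParameters,
    fixed: tuple[str, ...] = (),
) -> FitResult:
    """Least-squares recovery of SIT rates from an infested-house series.

    Minimises sum_t (I_model(t) - I_obs(t))^2 over the parameters not
    listed in ``fixed``, working on log-parameters so positivity holds by
    construction.  Only I is fitted; S and T are latent, initialised as
    S(0) = N - I_obs(0), T(0) = 0.  Nelder-Mead supplies a monotone
    accepted-iterate path (recorded in ``objective_history``); a bounded
    least-squares polish then sharpens the optimum.  Deterministic given
    ``init_guess``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    fixed = tuple(fixed)
    for name in fixed:
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter name in fixed: {name!r}")
    times, i_obs = _observed_series(observed)
    free = [p for p in _PARAM_NAMES if p not in fixed]

    i0 = float(i_obs[0])
    init_state = SITState(s=n_total - i0, i=i0, t=0.0, time=float(times[0]))
    horizon = float(times[-1] - times[0])
    dt = float(np.min(np.diff(times)))

    base = {p: getattr(init_guess, p) for p in _PARAM_NAMES}

    def model_i(theta_free: dict[str, float]) -> np.ndarray:
        params = SITParameters(**{**base, **theta_free})
        traj = simulate_sit(params, init_state, horizon=horizon, dt=dt)
        return np.interp(times, traj.times, traj.infested())

    def unpack(x: np.ndarray) -> dict[str, float]:
        return {p: float(np.exp(v)) for p, v in zip(free, x)}

    # Box on log-rates: monthly rates outside [1e-8, 50] are implausible
    # and make the ODE needlessly stiff when the optimizer explores the
    # weakly identified gamma/tau ridge.
    lo, hi = np.log(1e-8), np.log(50.0)
    cache: dict[bytes, float] = {}

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if np.any(x < lo) or np.any(x > hi):
            excess = np.sum(np.maximum(x - hi, 0) + np.maximum(lo - x, 0))
            return 1e30 * (1.0 + excess)
        key = x.tobytes()
        if key not in cache:
            cache[key] = float(np.sum((model_i(unpack(x)) - i_obs) ** 2))
        return cache[key]

    if not free:
        resid = objective(np.empty(0))
        return FitResult(
            params=init_guess,
            residual_norm=resid,
            converged=True,
            n_iter=0,
            objective_history=[resid],
        )

    x0 = np.log([base[p] for p in free])
    f0 = objective(x0)
    history = [f0]

    nm = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        callback=lambda xk: history.append(objective(xk)),
        options={
            "maxiter": 500,
            "xatol": 1e-9,
            "fatol": 1e-10 * max(f0, 1e-30),
            "adaptive": True,
        },
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        return model_i(unpack(x)) - i_obs

    polish = least_squares(
        residuals,
        np.clip(nm.x, lo + 1e-9, hi - 1e-9),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=200,
    )
    best_x, best_f = (polish.x, 2.0 * polish.cost) if 2.0 * polish.cost <= nm.fun else (nm.x, nm.fun)
    if best_f < history[-1]:
        history.append(best_f)
    params = SITParameters(**{**base, **unpack(best_x)})
    return FitResult(
        params=params,
        residual_norm=best_f,
        converged=bool(nm.success or polish.status > 0),
        n_iter=int(nm.nit),
        objective_history=history,
    )
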