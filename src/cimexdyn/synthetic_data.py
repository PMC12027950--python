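"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: county-level
household survey records (and their exact aggregates), noisy prevalence
time series from the SIT model, spatially autocorrelated environmental
raster stacks, a planted logistic suitability surface, and occurrence
points sampled proportionally to it.

Reproducibility: one global seed fans out to per-component child seeds
via ``numpy.random.SeedSequence(seed, spawn_key=(component_index,))``,
so each generator is independently reproducible from the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .parameter_inference import SurveySummary
from .sit_dynamics import SITParameters, SITState, Trajectory, endemic_equilibrium, simulate_sit
from .niche_suitability import CovariateStack, OccurrenceSet, SuitabilityRaster

__all__ = [
    "SyntheticConfig",
    "component_rng",
    "make_survey_data",
    "make_prevalence_series",
    "make_environmental_stack",
    "make_true_suitability",
    "sample_occurrences",
]

# Component indices for seed fan-out (stable across versions).
_COMPONENT = {"survey": 0, "series": 1, "stack": 2, "occurrences": 3}

DEFAULT_LAYER_NAMES = ("temp", "humidity", "pop_density", "elevation", "landcover")


def _default_county_params() -> dict[str, dict[str, SITParameters]]:
    """Illustrative county regimes over shared recovery/uptake/return rates.

    gamma = 0.1 (10-month spontaneous resolution), tau = 0.2 (20% of
    infested households start control per month), alpha = 0.25 (4-month
    control effectiveness); transmission beta varies by county and species
    to produce a coastal high-infestation county where species b
    dominates, a capital where both coexist at moderate levels, and two
    inland counties where species a dominates at low intensity.
    """
    shared = dict(gamma=0.1, tau=0.2, alpha=0.25)
    return {
        "Mombasa": {
            "a": SITParameters(beta=0.45, **shared),
            "b": SITParameters(beta=0.70, **shared),
        },
        "Nairobi": {
            "a": SITParameters(beta=0.45, **shared),
            "b": SITParameters(beta=0.45, **shared),
        },
        "Makueni": {
            "a": SITParameters(beta=0.50, **shared),
            "b": SITParameters(beta=0.33, **shared),
        },
        "Bomet": {
            "a": SITParameters(beta=0.48, **shared),
            "b": SITParameters(beta=0.33, **shared),
        },
    }


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for all generators.

    Defaults emulate the study design: 4 counties x 100 surveyed
    households, a 100 x 100 covariate grid with 5 layers, 200 presence
    points per species, 5% multiplicative observation noise.
    """

    seed: int = 0
    n_counties: int = 4
    n_households_per_county: int = 100
    true_params: dict[str, dict[str, SITParameters]] = field(
        default_factory=_default_county_params
    )
    grid_shape: tuple[int, int] = (100, 100)
    n_layers: int = 5
    layer_names: tuple[str, ...] = DEFAULT_LAYER_NAMES
    autocorr_length: int = 5
    planted_weights: dict[str, float] = field(
        default_factory=lambda: {"temp": 2.5, "humidity": 1.0, "pop_density": 1.0}
    )
    planted_weights_b: dict[str, float] = field(
        default_factory=lambda: {"temp": 1.0, "humidity": 2.5, "pop_density": 1.0}
    )
    # negative intercept -> the suitable niche covers ~10% of the landscape
    planted_intercept: float = -4.0
    n_presences: int = 200
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_counties <= 0 or self.n_households_per_county <= 0:
            raise ValueError("counts must be positive")
        if len(self.true_params) < self.n_counties:
            raise ValueError("true_params must cover every county")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.layer_names) != self.n_layers:
            raise ValueError("layer_names length must equal n_layers")


def component_rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    """Child RNG for one named component of the global seed."""
    idx = _COMPONENT[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx, extra)))


def _endemic_prevalence(params: SITParameters) -> float:
    eq = endemic_equilibrium(params, 1.0)
    return 0.0 if eq is None else eq.i


def make_survey_data(cfg: SyntheticConfig) -> tuple[pd.DataFrame, list[SurveySummary]]:
    """Draw household records and aggregate them into per-county summaries.

    Infestation status per species is Bernoulli with the endemic
    prevalence implied by the county's true parameters; a treatment
    indicator is drawn (probability tau per month) for infested
    households; every respondent reports a control-effectiveness duration
    (exponential, mean 1/alpha) and a self-recovery duration (exponential,
    mean 1/gamma).  Summaries are exact aggregates of the records.
    """
    rng = component_rng(cfg.seed, "survey")
    counties = list(cfg.true_params)[: cfg.n_counties]
    records = []
    summaries = []
    for county in counties:
        pa, pb = cfg.true_params[county]["a"], cfg.true_params[county]["b"]
        n = cfg.n_households_per_county
        prev_a, prev_b = _endemic_prevalence(pa), _endemic_prevalence(pb)
        infested_a = rng.random(n) < prev_a
        infested_b = rng.random(n) < prev_b
        infested_any = infested_a | infested_b
        treats = np.where(infested_any, rng.random(n) < pa.tau, False)
        eff = rng.exponential(1.0 / pa.alpha, size=n)
        recov = rng.exponential(1.0 / pa.gamma, size=n)
        df = pd.DataFrame(
            {
                "county": county,
                "household_id": np.arange(n),
                "infested_a": infested_a,
                "infested_b": infested_b,
                "treats": treats,
                "effectiveness_months": eff,
                "self_recovery_months": recov,
            }
        )
        records.append(df)
        n_inf = int(infested_any.sum())
        summaries.append(
            SurveySummary(
                county_label=county,
                n_respondents=n,
                prevalence_a=float(infested_a.mean()),
                prevalence_b=float(infested_b.mean()),
                treat_fraction=float(treats.sum() / n_inf) if n_inf else 0.0,
                effectiveness_months=float(eff.mean()),
                self_recovery_months=float(recov.mean()),
            )
        )
    return pd.concat(records, ignore_index=True), summaries


def make_prevalence_series(
    true_params: SITParameters,
    init: SITState,
    horizon: float = 24.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    dt: float = 1.0,
) -> Trajectory:
    """Noisy monthly infested-house series from the SIT model.

    I_obs(t) = I_model(t) * exp(eps_t) with eps_t ~ Normal(0, noise_sd);
    noise_sd = 0 returns the exact model curve.  S and T are left as the
    model values of the noise-free run (the observer sees only I).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traj = simulate_sit(true_params, init, horizon=horizon, dt=dt)
    states = traj.states.copy()
    if noise_sd > 0:
        rng = component_rng(seed, "series")
        eps = rng.normal(0.0, noise_sd, size=len(traj.times))
        states[:, 1] = states[:, 1] * np.exp(eps)
    return Trajectory(times=traj.times, states=states, n_total=traj.n_total)


def make_environmental_stack(
    grid_shape: tuple[int, int] = (100, 100),
    n_layers: int = 5,
    autocorr_length: int = 5,
    seed: int = 0,
    layer_names: tuple[str, ...] | None = None,
) -> CovariateStack:
    """Independent spatially autocorrelated layers, standardized.

    Each layer is white Gaussian noise smoothed with a moving-average
    kernel of width ``autocorr_length`` (width 1 leaves the noise
    untouched), then standardized to mean 0 / variance 1 over the grid.
    """
    nrows, ncols = grid_shape
    if nrows < 10 or ncols < 10:
        raise ValueError("grid must be at least 10 x 10")
    if autocorr_length >= min(nrows, ncols):
        raise ValueError("autocorr_length must be smaller than the grid dimensions")
    if autocorr_length < 1:
        raise ValueError("autocorr_length must be >= 1")
    if layer_names is None:
        layer_names = tuple(
            DEFAULT_LAYER_NAMES[k] if k < len(DEFAULT_LAYER_NAMES) else f"noise_{k}"
            for k in range(n_layers)
        )
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length must equal n_layers")
    layers = {}
    for k, name in enumerate(layer_names):
        rng = component_rng(seed, "stack", extra=k)
        noise = rng.standard_normal(grid_shape)
        smooth = uniform_filter(noise, size=autocorr_length, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        layers[name] = smooth
    return CovariateStack(layers, cell_size=1.0, origin=(0.0, float(nrows)))


def make_true_suitability(
    stack: CovariateStack,
    planted_weights: dict[str, float],
    intercept: float = 0.0,
) -> SuitabilityRaster:
    """Logistic transform of a weighted sum of layers — planted truth.

    A negative ``intercept`` makes the niche rare (most of the landscape
    unsuitable), which is typical of real species distributions and is
    what makes presence points discriminable from uniform background.
    """
    unknown = [n for n in planted_weights if n not in stack.layers]
    if unknown:
        raise ValueError(f"planted weights name unknown layer(s): {unknown}")
    z = np.full(stack.shape, float(intercept))
    for name, w in planted_weights.items():
        z = z + w * stack.layers[name]
    return SuitabilityRaster(
        values=np.where(stack.nodata_mask, 0.0, expit(z)),
        nodata_mask=stack.nodata_mask.copy(),
        cell_size=stack.cell_size,
        origin=stack.origin,
    )


def sample_occurrences(
    true_raster: SuitabilityRaster,
    n_presences: int,
    seed: int = 0,
    species_label: str = "species",
) -> OccurrenceSet:
    """Presence points at cell centers, drawn with probability
    proportional to the true suitability score (size-biased sampling)."""
    if n_presences < 1:
        raise ValueError("n_presences must be >= 1")
    weights = np.where(true_raster.nodata_mask, 0.0, true_raster.values).ravel()
    total = weights.sum()
    if total == 0:
        raise ValueError("cannot sample occurrences from an all-zero raster")
    rng = component_rng(seed, "occurrences")
    flat = rng.choice(weights.size, size=n_presences, replace=True, p=weights / total)
    rows, cols = np.unravel_index(flat, true_raster.values.shape)
    x0, y0 = true_raster.origin
    cs = true_raster.cell_size
    points = np.stack(
        [x0 + (cols + 0.5) * cs, y0 - (rows + 0.5) * cs], axis=1
    )
    return OccurrenceSet(points=points, species_label=species_label)
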