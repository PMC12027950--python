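"""End-to-end orchestration: synth -> (simulate | fit) and
synth -> filter-vars -> train -> overlap, with all artifacts on disk.

A :class:`RunConfig` selects stages and overrides per-stage defaults;
:func:`run_pipeline` executes the selected stages in dependency order and
writes a machine-readable manifest (paths, seeds, metrics, config hash).
Metrics live only in the manifest, never parsed from logs; rerunning the
same config reproduces identical metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .niche_suitability import (
    CovariateStack,
    OccurrenceSet,
    co_suitability_map,
    jackknife_importance,
    pearson_collinearity_filter,
    read_ascii_grid,
    subsample_ensemble,
    write_ascii_grid,
)
from .parameter_inference import SurveySummary, fit_sit
from .sit_dynamics import (
    SITParameters,
    SITState,
    TwoSpeciesParameters,
    simulate_two_species,
)
from .synthetic_data import (
    SyntheticConfig,
    make_environmental_stack,
    make_prevalence_series,
    make_survey_data,
    make_true_suitability,
    sample_occurrences,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("synth", "simulate", "fit", "filter-vars", "train", "overlap")

_BLOCK_KEYS = {
    "synth": {
        "n_counties",
        "n_households_per_county",
        "grid_shape",
        "n_layers",
        "autocorr_length",
        "n_presences",
        "noise_sd",
    },
    "simulate": {"horizon", "dt", "kappa_ab", "kappa_ba", "init_infested_frac", "n_total"},
    "fit": {"county", "species", "fix", "init_guess_scale"},
    "filter_vars": {"threshold"},
    "train": {"train_frac", "n_reps", "n_background"},
    "overlap": {"threshold"},
}

_BLOCK_DEFAULTS = {
    "simulate": {
        "horizon": 24.0,
        "dt": 0.1,
        "kappa_ab": 0.25,
        "kappa_ba": 0.25,
        "init_infested_frac": 0.05,
        "n_total": 100.0,
    },
    "fit": {"county": None, "species": "a", "fix": ["alpha"], "init_guess_scale": 2.0},
    "filter_vars": {"threshold": 0.7},
    "train": {"train_frac": 0.7, "n_reps": 3, "n_background": None},
    "overlap": {"threshold": 0.4},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    log_level: str = "INFO"
    synth: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    filter_vars: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; known: {list(ALL_STAGES)}")
        self.stages = tuple(self.stages)
        for block, keys in _BLOCK_KEYS.items():
            bad = set(getattr(self, block)) - keys
            if bad:
                raise ValueError(f"unknown keys in {block!r} block: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {
            "out_dir", "stages", "seed", "log_level",
            "synth", "simulate", "fit", "filter_vars", "train", "overlap",
        }
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    def block(self, name: str) -> dict:
        merged = dict(_BLOCK_DEFAULTS.get(name, {}))
        merged.update(getattr(self, name))
        return merged

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(artifacts: dict, key: str, stage: str, upstream: str):
    if key not in artifacts:
        raise RuntimeError(
            f"stage {stage!r} needs artifact {key!r}; run stage {upstream!r} first"
        )
    return artifacts[key]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
        "paths": {},
    }
    artifacts: dict = {}
    try:
        for stage in ALL_STAGES:  # fixed dependency order
            if stage not in config.stages:
                continue
            runner = _STAGE_RUNNERS[stage]
            metrics = runner(config, artifacts, out, manifest["paths"])
            manifest["stages"][stage] = metrics
            logger.info("stage %s done: %s", stage, metrics)
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    manifest["paths"]["manifest"] = str(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _stage_synth(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    overrides = dict(config.block("synth"))
    if "grid_shape" in overrides:
        overrides["grid_shape"] = tuple(overrides["grid_shape"])
    cfg = SyntheticConfig(seed=config.seed, **overrides)
    artifacts["synth_cfg"] = cfg

    records, summaries = make_survey_data(cfg)
    records.to_csv(out / "survey_records.csv", index=False)
    SurveySummary.table_to_csv(summaries, out / "survey_summaries.csv")
    artifacts["summaries"] = summaries

    stack = make_environmental_stack(
        cfg.grid_shape, cfg.n_layers, cfg.autocorr_length, cfg.seed, cfg.layer_names
    )
    artifacts["stack"] = stack
    stack_dir = out / "stack"
    stack_dir.mkdir(exist_ok=True)
    for name, layer in stack.layers.items():
        # standardized layers are unbounded, so bypass the [0,1] container
        _write_layer(layer, stack, stack_dir / f"{name}.asc")
    occs = {}
    for label, weights in (("a", cfg.planted_weights), ("b", cfg.planted_weights_b)):
        truth = make_true_suitability(stack, weights, intercept=cfg.planted_intercept)
        occ = sample_occurrences(
            truth, cfg.n_presences, seed=cfg.seed, species_label=label
        )
        occ.to_csv(out / f"occurrences_{label}.csv")
        occs[label] = occ
    artifacts["occurrences"] = occs

    fit_block = config.block("fit")
    county = fit_block["county"] or list(cfg.true_params)[0]
    truth = cfg.true_params[county][fit_block["species"]]
    n_total = float(cfg.n_households_per_county)
    init = SITState(s=0.95 * n_total, i=0.05 * n_total, t=0.0)
    series = make_prevalence_series(
        truth, init, horizon=24.0, noise_sd=cfg.noise_sd, seed=cfg.seed
    )
    series.to_csv(out / "prevalence_series.csv")
    artifacts["series"] = (series, truth, n_total)

    paths.update(
        {
            "survey_records": str(out / "survey_records.csv"),
            "survey_summaries": str(out / "survey_summaries.csv"),
            "stack_dir": str(stack_dir),
            "occurrences_a": str(out / "occurrences_a.csv"),
            "occurrences_b": str(out / "occurrences_b.csv"),
            "prevalence_series": str(out / "prevalence_series.csv"),
        }
    )
    return {
        "n_counties": cfg.n_counties,
        "n_records": int(len(records)),
        "prevalence_a": [s.prevalence_a for s in summaries],
        "prevalence_b": [s.prevalence_b for s in summaries],
    }


def _write_layer(layer: np.ndarray, stack: CovariateStack, path: Path) -> None:
    nrows = layer.shape[0]
    x0, y0 = stack.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.shape[1]}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 - nrows * stack.cell_size!r}\n")
        fh.write(f"cellsize {stack.cell_size!r}\n")
        fh.write("NODATA_value -9999.0\n")
        for row in np.where(stack.nodata_mask, -9999.0, layer):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _stage_simulate(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    cfg = _require(artifacts, "synth_cfg", "simulate", "synth")
    blk = config.block("simulate")
    n = float(blk["n_total"])
    frac = float(blk["init_infested_frac"])
    metrics = {}
    for county, species_params in cfg.true_params.items():
        params = TwoSpeciesParameters(
            species_a=species_params["a"],
            species_b=species_params["b"],
            kappa_ab=float(blk["kappa_ab"]),
            kappa_ba=float(blk["kappa_ba"]),
        )
        init = SITState(s=(1 - frac) * n, i=frac * n, t=0.0)
        traj = simulate_two_species(
            params, init, init, n_total=n, horizon=float(blk["horizon"]), dt=float(blk["dt"])
        )
        path = out / f"trajectory_{county}.csv"
        traj.to_csv(path)
        paths[f"trajectory_{county}"] = str(path)
        metrics[county] = {
            "final_I_a": float(traj.infested(0)[-1]),
            "final_I_b": float(traj.infested(1)[-1]),
        }
    return metrics


def _stage_fit(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    series, truth, n_total = _require(artifacts, "series", "fit", "synth")
    blk = config.block("fit")
    scale = float(blk["init_guess_scale"])
    guess = SITParameters(
        beta=scale * truth.beta,
        gamma=scale * truth.gamma,
        tau=scale * truth.tau,
        alpha=truth.alpha,
    )
    result = fit_sit(series, n_total, guess, fixed=tuple(blk["fix"]))
    fitted = result.params
    report = {
        "fitted": {p: getattr(fitted, p) for p in ("beta", "gamma", "tau", "alpha")},
        "true": {p: getattr(truth, p) for p in ("beta", "gamma", "tau", "alpha")},
        "relative_error": {
            p: abs(getattr(fitted, p) - getattr(truth, p)) / getattr(truth, p)
            for p in ("beta", "gamma", "tau")
        },
        "residual_norm": result.residual_norm,
        "converged": result.converged,
        "n_iter": result.n_iter,
    }
    with open(out / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    paths["fit_report"] = str(out / "fit_report.json")
    return report


def _stage_filter_vars(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    stack = _require(artifacts, "stack", "filter-vars", "synth")
    retained = pearson_collinearity_filter(
        stack, threshold=float(config.block("filter_vars")["threshold"])
    )
    artifacts["retained"] = retained
    with open(out / "retained_layers.json", "w") as fh:
        json.dump(retained, fh)
    paths["retained_layers"] = str(out / "retained_layers.json")
    return {"retained": retained, "n_dropped": len(stack.names) - len(retained)}


def _stage_train(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    stack = _require(artifacts, "stack", "train", "synth")
    occs = _require(artifacts, "occurrences", "train", "synth")
    retained = artifacts.get("retained", stack.names)
    sub = stack.subset(retained)
    blk = config.block("train")
    metrics = {}
    ensembles = {}
    for label, occ in occs.items():
        ensemble, aucs = subsample_ensemble(
            sub,
            occ,
            train_frac=float(blk["train_frac"]),
            n_reps=int(blk["n_reps"]),
            n_background=blk["n_background"],
            seed=config.seed,
        )
        imp = jackknife_importance(sub, occ, n_background=blk["n_background"], seed=config.seed)
        path = out / f"ensemble_{label}.asc"
        write_ascii_grid(ensemble, path)
        paths[f"ensemble_{label}"] = str(path)
        ensembles[label] = ensemble
        metrics[label] = {
            "test_aucs": [float(a) for a in aucs],
            "jackknife": {
                "auc_only": imp.auc_only,
                "auc_without": imp.auc_without,
                "top_variable": imp.top_variable(),
            },
        }
    artifacts["ensembles"] = ensembles
    return metrics


def _stage_overlap(config: RunConfig, artifacts: dict, out: Path, paths: dict) -> dict:
    ensembles = _require(artifacts, "ensembles", "overlap", "train")
    threshold = float(config.block("overlap")["threshold"])
    overlap, jaccard = co_suitability_map(ensembles["a"], ensembles["b"], threshold)
    path = out / "co_suitability.asc"
    write_ascii_grid(overlap, path)
    paths["co_suitability"] = str(path)
    return {
        "jaccard": jaccard,
        "threshold": threshold,
        "n_overlap_cells": int(overlap.mask.sum()),
    }


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "filter-vars": _stage_filter_vars,
    "train": _stage_train,
    "overlap": _stage_overlap,
}
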