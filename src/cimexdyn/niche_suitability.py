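"""Habitat-suitability mapping and two-species niche overlap.

The workflow mirrors standard presence-background species distribution
modelling: filter collinear covariates by Pearson correlation, train a
suitability learner on presence points against randomly sampled
background cells, validate with repeated 70/30 sub-sample splits and the
threshold-independent rank AUC, rank variables by jackknife retraining,
classify the continuous suitability surface into five ordinal bands, and
quantify co-suitability of two species with the Jaccard index of their
binarized maps.

The learner itself is a penalized logistic presence-vs-background
discriminator on standardized linear + quadratic covariate features — a
deliberately simple, pluggable surface estimator with probability-scale
output in [0, 1].

Rasters are row-major with row 0 the northernmost row; ``origin`` is the
(x, y) of the outer (north-west) corner of cell (0, 0).  On disk they are
plain ESRI ASCII grids, human-readable and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "SuitabilityRaster",
    "BinaryRaster",
    "ClassifiedRaster",
    "CovariateStack",
    "OccurrenceSet",
    "SuitabilityModel",
    "ImportanceTable",
    "pearson_collinearity_filter",
    "train_suitability_model",
    "predict_suitability",
    "subsample_ensemble",
    "roc_auc",
    "jackknife_importance",
    "classify_suitability",
    "binarize",
    "jaccard_index",
    "co_suitability_map",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_CORR_THRESHOLD = 0.7
DEFAULT_BINARIZE_THRESHOLD = 0.4  # "moderate or better"
DEFAULT_TRAIN_FRAC = 0.7
DEFAULT_N_REPS = 3
CLASS_LABELS = ("very low", "low", "moderate", "high", "very high")

_NODATA = -9999.0


# ---------------------------------------------------------------------------
# Raster containers and ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityRaster:
    """Gridded suitability scores in [0, 1] with a nodata mask."""

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        valid = self.values[~self.nodata_mask]
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 1):
            raise ValueError("suitability scores must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryRaster:
    """Boolean suitability mask aligned to its source raster geometry."""

    mask: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.mask.shape != self.nodata_mask.shape:
            raise ValueError("mask and nodata_mask shapes differ")


@dataclass
class ClassifiedRaster:
    """Ordinal suitability classes; codes 0..4 index CLASS_LABELS, -1 nodata."""

    codes: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    labels: tuple[str, ...] = CLASS_LABELS


class CovariateStack:
    """Named environmental layers sharing one grid, cell size and mask."""

    def __init__(
        self,
        layers: dict[str, np.ndarray],
        nodata_mask: np.ndarray | None = None,
        cell_size: float = 1.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> None:
        if not layers:
            raise ValueError("stack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        arrays = {k: np.asarray(v, dtype=float) for k, v in layers.items()}
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        shape = shapes.pop()
        if nodata_mask is None:
            nodata_mask = np.zeros(shape, dtype=bool)
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
        if nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape differs from layers")
        self.layers = arrays
        self.nodata_mask = nodata_mask
        self.cell_size = float(cell_size)
        self.origin = (float(origin[0]), float(origin[1]))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    def subset(self, names: list[str]) -> "CovariateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise ValueError(f"unknown layers: {missing}")
        return CovariateStack(
            {n: self.layers[n] for n in names},
            self.nodata_mask,
            self.cell_size,
            self.origin,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); row 0 is north."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 - (row + 0.5) * self.cell_size,
        )


@dataclass
class OccurrenceSet:
    """Presence points (x, y) for one species."""

    points: np.ndarray
    species_label: str = "species"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "species": self.species_label,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species_label: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if species_label is not None:
            df = df[df["species"].astype(str) == species_label]
        else:
            species_label = str(df["species"].iloc[0])
        return cls(points=df[["x", "y"]].to_numpy(), species_label=species_label)

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"species": self.species_label},
            }
            for x, y in self.points
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "OccurrenceSet":
        with open(path) as fh:
            gj = json.load(fh)
        pts = [f["geometry"]["coordinates"] for f in gj["features"]]
        label = gj["features"][0]["properties"].get("species", "species")
        return cls(points=np.array(pts, dtype=float), species_label=label)


def write_ascii_grid(raster, path, nodata: float = _NODATA) -> None:
    """Write a raster (suitability or binary) as an ESRI ASCII grid."""
    if isinstance(raster, BinaryRaster):
        values = raster.mask.astype(float)
    else:
        values = raster.values
    nrows, ncols = values.shape
    x0, y0 = raster.origin
    out = np.where(raster.nodata_mask, nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 - nrows * raster.cell_size!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:  # row 0 = north, the ASCII grid convention
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> SuitabilityRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cell)
    return SuitabilityRaster(values=values, nodata_mask=mask, cell_size=cell, origin=origin)


# ---------------------------------------------------------------------------
# Collinearity filtering
# ---------------------------------------------------------------------------


def pearson_collinearity_filter(
    stack: CovariateStack, threshold: float = DEFAULT_CORR_THRESHOLD
) -> list[str]:
    """Greedy elimination of collinear layers by pairwise Pearson |r|.

    While any retained pair exceeds ``threshold``, the member of the worst
    pair with the larger mean |r| to all other retained layers is dropped
    (ties broken by layer-name order).  Constant layers are dropped with a
    warning, never an exception.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    valid = ~stack.nodata_mask
    names = []
    columns = []
    for name in stack.names:
        col = stack.layers[name][valid]
        if np.std(col) == 0:
            logger.warning("dropping constant layer %r (zero variance)", name)
            continue
        names.append(name)
        columns.append(col)
    if len(names) <= 1:
        return names
    r = np.abs(np.corrcoef(np.stack(columns)))
    keep = list(range(len(names)))
    while len(keep) > 1:
        sub = r[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 0.0)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= threshold:
            break
        i, j = keep[worst[0]], keep[worst[1]]
        mean_i = sub[worst[0]].sum() / (len(keep) - 1)
        mean_j = sub[worst[1]].sum() / (len(keep) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # tie: drop the lexicographically later name
            drop = max(i, j, key=lambda k: names[k])
        keep.remove(drop)
    return [names[k] for k in keep]


# ---------------------------------------------------------------------------
# Presence-background suitability learner
# ---------------------------------------------------------------------------


def _presence_cells(stack: CovariateStack, occ: OccurrenceSet) -> np.ndarray:
    """Snap occurrence points to containing cells; reject nodata/outside."""
    nrows, ncols = stack.shape
    cells = []
    n_rejected = 0
    for x, y in occ.points:
        row, col = stack.cell_of(x, y)
        if not (0 <= row < nrows and 0 <= col < ncols) or stack.nodata_mask[row, col]:
            n_rejected += 1
            continue
        cells.append((row, col))
    if n_rejected:
        logger.warning(
            "rejected %d occurrence point(s) outside the grid or on nodata cells",
            n_rejected,
        )
    if not cells:
        raise ValueError("no occurrence point falls on a valid cell")
    return np.array(cells, dtype=int)


def _features_at(stack: CovariateStack, cells: np.ndarray) -> np.ndarray:
    """Linear + quadratic covariate features at (row, col) cells."""
    cols = [stack.layers[n][cells[:, 0], cells[:, 1]] for n in stack.names]
    x = np.stack(cols, axis=1)
    return np.concatenate([x, x**2], axis=1)


def _sample_background(
    stack: CovariateStack, presence_cells: np.ndarray, n_background: int, rng
) -> np.ndarray:
    valid = ~stack.nodata_mask
    flat_valid = np.flatnonzero(valid.ravel())
    presence_flat = set(presence_cells[:, 0] * stack.shape[1] + presence_cells[:, 1])
    candidates = np.array([f for f in flat_valid if f not in presence_flat])
    if candidates.size == 0:
        raise ValueError("no background cells available outside presences")
    chosen = rng.choice(candidates, size=n_background, replace=True)
    return np.stack(np.unravel_index(chosen, stack.shape), axis=1)


@dataclass
class SuitabilityModel:
    """Fitted presence-background discriminator (opaque scorer to [0, 1])."""

    layer_names: list[str]
    scaler: StandardScaler
    classifier: LogisticRegression

    def score_cells(self, stack: CovariateStack, cells: np.ndarray) -> np.ndarray:
        missing = [n for n in self.layer_names if n not in stack.layers]
        if missing:
            raise ValueError(f"stack is missing layer(s) {missing}")
        sub = stack.subset(self.layer_names)
        feats = self.scaler.transform(_features_at(sub, cells))
        return self.classifier.predict_proba(feats)[:, 1]


def train_suitability_model(
    stack: CovariateStack,
    occ: OccurrenceSet,
    n_background: int | None = None,
    seed: int = 0,
    background_cells: np.ndarray | None = None,
) -> SuitabilityModel:
    """Fit the penalized logistic presence-vs-background model.

    Deterministic given ``seed`` (used only for background sampling; pass
    ``background_cells`` explicitly to reuse a fixed background).
    Requires at least two presence cells with distinct covariates.
    """
    presence = _presence_cells(stack, occ)
    if n_background is None:
        n_background = 10 * len(presence)
    feats_p = _features_at(stack, presence)
    if np.unique(feats_p, axis=0).shape[0] < 2:
        raise ValueError(
            "degenerate input: fewer than 2 presence cells with distinct covariates"
        )
    if background_cells is None:
        rng = np.random.default_rng(seed)
        background_cells = _sample_background(stack, presence, n_background, rng)
    feats_b = _features_at(stack, background_cells)
    x = np.concatenate([feats_p, feats_b])
    y = np.concatenate([np.ones(len(feats_p)), np.zeros(len(feats_b))])
    scaler = StandardScaler().fit(x)
    # balanced class weights: scores are comparable to a 50% presence
    # prior regardless of the background:presence ratio, so the [0,1]
    # output is interpretable against fixed suitability thresholds
    clf = LogisticRegression(C=1.0, class_weight="balanced", solver="lbfgs", max_iter=1000)
    clf.fit(scaler.transform(x), y)
    return SuitabilityModel(layer_names=stack.names, scaler=scaler, classifier=clf)


def predict_suitability(model: SuitabilityModel, stack: CovariateStack) -> SuitabilityRaster:
    """Score every non-masked cell; nodata propagates."""
    valid = ~stack.nodata_mask
    cells = np.stack(np.nonzero(valid), axis=1)
    values = np.zeros(stack.shape, dtype=float)
    if len(cells):
        values[cells[:, 0], cells[:, 1]] = model.score_cells(stack, cells)
    return SuitabilityRaster(
        values=values,
        nodata_mask=stack.nodata_mask.copy(),
        cell_size=stack.cell_size,
        origin=stack.origin,
    )


# ---------------------------------------------------------------------------
# Validation: rank AUC, sub-sample ensemble, jackknife importance
# ---------------------------------------------------------------------------


def roc_auc(presence_scores, background_scores) -> float:
    """Rank (Mann-Whitney) AUC: fraction of (presence, background) pairs
    with presence > background, ties counted one half.  Exact pair-count
    semantics via sorted search, threshold-independent."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("score lists must be non-empty")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    b_sorted = np.sort(b)
    greater = np.searchsorted(b_sorted, p, side="left")
    ties = np.searchsorted(b_sorted, p, side="right") - greater
    return float((greater.sum() + 0.5 * ties.sum()) / (p.size * b.size))


def _split_presences(presence: np.ndarray, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n = len(presence)
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train fraction {train_frac} leaves an empty partition for {n} presences"
        )
    perm = rng.permutation(n)
    return presence[perm[:n_train]], presence[perm[n_train:]]


def subsample_ensemble(
    stack: CovariateStack,
    occ: OccurrenceSet,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_reps: int = DEFAULT_N_REPS,
    n_background: int | None = None,
    seed: int = 0,
) -> tuple[SuitabilityRaster, list[float]]:
    """Repeated sub-sample validation and cellwise-mean ensemble.

    Each replicate holds out (1 - train_frac) of the presences, trains on
    the rest against fresh background, and scores the held-out presences
    against an independent fresh background sample for the test AUC.  The
    ensemble raster is the cellwise mean of the replicate predictions.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    presence = _presence_cells(stack, occ)
    if n_background is None:
        n_background = 10 * len(presence)
    ss = np.random.SeedSequence(seed)
    rasters, aucs = [], []
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng_split, rng_train_bg, rng_test_bg = (
            np.random.default_rng(s) for s in child.spawn(3)
        )
        train_cells, test_cells = _split_presences(presence, train_frac, rng_split)
        train_bg = _sample_background(stack, train_cells, n_background, rng_train_bg)
        train_occ = OccurrenceSet(
            points=np.array([stack.cell_center(r, c) for r, c in train_cells]),
            species_label=occ.species_label,
        )
        model = train_suitability_model(
            stack, train_occ, n_background=n_background, background_cells=train_bg
        )
        test_bg = _sample_background(stack, test_cells, n_background, rng_test_bg)
        auc = roc_auc(
            model.score_cells(stack, test_cells), model.score_cells(stack, test_bg)
        )
        aucs.append(auc)
        rasters.append(predict_suitability(model, stack))
    mean_values = np.mean([r.values for r in rasters], axis=0)
    ensemble = SuitabilityRaster(
        values=np.where(stack.nodata_mask, 0.0, mean_values),
        nodata_mask=stack.nodata_mask.copy(),
        cell_size=stack.cell_size,
        origin=stack.origin,
    )
    return ensemble, aucs


@dataclass
class ImportanceTable:
    """Jackknife variable importance: AUC with only / without each layer."""

    auc_only: dict[str, float]
    auc_without: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.auc_only, self.auc_without):
            for name, v in table.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"AUC for {name!r} outside [0, 1]: {v}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"auc_only": self.auc_only, "auc_without": self.auc_without}
        ).rename_axis("variable")

    def top_variable(self) -> str:
        return max(self.auc_only, key=self.auc_only.get)


def jackknife_importance(
    stack: CovariateStack,
    occ: OccurrenceSet,
    n_background: int | None = None,
    seed: int = 0,
    train_frac: float = DEFAULT_TRAIN_FRAC,
) -> ImportanceTable:
    """Retrain with each variable alone and with each variable omitted.

    One shared 70/30 presence split and one shared background pair are
    used across all variables so the AUCs are comparable.
    """
    if len(stack.names) < 2:
        raise ValueError("jackknife needs >= 2 layers (without-variable model undefined)")
    presence = _presence_cells(stack, occ)
    if n_background is None:
        n_background = 10 * len(presence)
    ss = np.random.SeedSequence(seed)
    rng_split, rng_train_bg, rng_test_bg = (np.random.default_rng(s) for s in ss.spawn(3))
    train_cells, test_cells = _split_presences(presence, train_frac, rng_split)
    train_bg = _sample_background(stack, train_cells, n_background, rng_train_bg)
    test_bg = _sample_background(stack, test_cells, n_background, rng_test_bg)
    train_occ = OccurrenceSet(
        points=np.array([stack.cell_center(r, c) for r, c in train_cells]),
        species_label=occ.species_label,
    )

    def auc_for(names: list[str]) -> float:
        sub = stack.subset(names)
        model = train_suitability_model(
            sub, train_occ, n_background=n_background, background_cells=train_bg
        )
        return roc_auc(
            model.score_cells(sub, test_cells), model.score_cells(sub, test_bg)
        )

    auc_only = {v: auc_for([v]) for v in stack.names}
    auc_without = {
        v: auc_for([n for n in stack.names if n != v]) for v in stack.names
    }
    return ImportanceTable(auc_only=auc_only, auc_without=auc_without)


# ---------------------------------------------------------------------------
# Classification, binarization, Jaccard co-suitability
# ---------------------------------------------------------------------------


def classify_suitability(raster: SuitabilityRaster) -> ClassifiedRaster:
    """Equal-interval fifths: [0,0.2) very low ... [0.8,1.0] very high."""
    codes = np.clip(np.floor(raster.values * 5).astype(int), 0, 4)
    codes = np.where(raster.nodata_mask, -1, codes)
    return ClassifiedRaster(
        codes=codes,
        nodata_mask=raster.nodata_mask.copy(),
        cell_size=raster.cell_size,
        origin=raster.origin,
    )


def binarize(
    raster: SuitabilityRaster, threshold: float = DEFAULT_BINARIZE_THRESHOLD
) -> BinaryRaster:
    """Suitable where score >= threshold (moderate-or-better by default)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    mask = (raster.values >= threshold) & ~raster.nodata_mask
    return BinaryRaster(
        mask=mask,
        nodata_mask=raster.nodata_mask.copy(),
        cell_size=raster.cell_size,
        origin=raster.origin,
    )


def _same_geometry(a, b) -> bool:
    return (
        a.nodata_mask.shape == b.nodata_mask.shape
        and a.cell_size == b.cell_size
        and a.origin == b.origin
    )


def jaccard_index(u: BinaryRaster, v: BinaryRaster) -> float:
    """|U ∩ V| / |U ∪ V| over non-masked cells; undefined for empty union."""
    if not _same_geometry(u, v):
        raise ValueError("binary rasters must share geometry")
    valid = ~(u.nodata_mask | v.nodata_mask)
    inter = int(np.count_nonzero(u.mask & v.mask & valid))
    union = int(np.count_nonzero((u.mask | v.mask) & valid))
    if union == 0:
        raise ValueError("Jaccard index undefined for an empty union")
    return inter / union


def co_suitability_map(
    a: SuitabilityRaster,
    b: SuitabilityRaster,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> tuple[BinaryRaster, float]:
    """Cellwise conjunction of the two binarized maps plus their Jaccard."""
    if not _same_geometry(a, b):
        raise ValueError("suitability rasters must share geometry")
    ba, bb = binarize(a, threshold), binarize(b, threshold)
    overlap = BinaryRaster(
        mask=ba.mask & bb.mask,
        nodata_mask=(a.nodata_mask | b.nodata_mask),
        cell_size=a.cell_size,
        origin=a.origin,
    )
    return overlap, jaccard_index(ba, bb)
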