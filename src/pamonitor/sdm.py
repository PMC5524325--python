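"""Habitat suitability modelling with target-group backgrounds.

Builds per-species, per-year, per-radius suitability models from survey
presences. Because road surveys share one spatial bias across all species,
pseudo-absences for a target species are taken from the presence points of
the *other* surveyed species (the target-group background), which cancels
the survey bias instead of contrasting it with a uniform background.

Models are calibrated on repeated stratified 70/30 splits, evaluated with
AUC, maximized TSS and kappa, combined into a weighted-mean ensemble
(weights proportional to a skill metric, TSS by default), projected at a
coarse analysis grain, and scored with the continuous Boyce index — a
presence-only metric given by the Spearman rank correlation between
moving-window suitability midpoints and the predicted-to-expected presence
ratio in each window. The Boyce score of the projected ensemble selects
the best habitat-characterization radius per species.

The learner roster is a small registry (a penalized logistic scorer and a
surface range envelope); additional learners can be registered, the
protocol is agnostic to their internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grid import GridGeometry
from .predictors import PREDICTOR_CLASSES, PredictorStack

__all__ = [
    "TooFewPresencesError",
    "ConstantResponseError",
    "Undefined",
    "ModellingTable",
    "SplitPlan",
    "EvalScores",
    "SuitabilityMap",
    "EnsembleResult",
    "build_modelling_table",
    "make_splits",
    "get_learner",
    "register_learner",
    "fit_and_predict",
    "evaluate_model",
    "boyce_index",
    "build_ensemble",
    "select_best_level",
    "plan_experiment",
    "ensemble_for",
    "ensemble_boyce",
]


class TooFewPresencesError(ValueError):
    """The target species has too few presences to model."""

    def __init__(self, species: str, count: int, minimum: int):
        self.species = species
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"{species}: {count} presences; need more than {minimum}"
        )


class ConstantResponseError(ValueError):
    """A calibration subset contained a single response class."""


@dataclass(frozen=True)
class Undefined:
    """Typed marker for scores that cannot be computed (never silently 0)."""

    reason: str


def _is_defined(value) -> bool:
    return not isinstance(value, Undefined) and value is not None


@dataclass
class ModellingTable:
    """Presence/background rows with predictors for one species-year-radius.

    ``frame`` columns: ``response`` (1 presence, 0 background), the
    predictor columns for this radius, and ``provenance`` (which species
    contributed each row).
    """

    frame: pd.DataFrame
    target: str
    year: int
    radius: float
    predictor_columns: tuple[str, ...]

    @property
    def n_presences(self) -> int:
        return int((self.frame["response"] == 1).sum())

    @property
    def n_backgrounds(self) -> int:
        return int((self.frame["response"] == 0).sum())

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.frame[list(self.predictor_columns)].to_numpy(dtype=float)
        y = self.frame["response"].to_numpy(dtype=int)
        return x, y


@dataclass(frozen=True)
class SplitPlan:
    replicate: int
    calibration: np.ndarray
    validation: np.ndarray
    seed: int


@dataclass
class EvalScores:
    """Discrimination metrics for one model (thresholded ones maximized
    over a fixed 0.01 threshold grid, with the peak threshold recorded)."""

    auc: float
    tss: float
    kappa: float
    tss_threshold: float
    kappa_threshold: float
    boyce: float | Undefined | None = None

    def metric(self, name: str) -> float:
        value = getattr(self, name)
        if not _is_defined(value):
            raise ValueError(f"metric {name!r} is undefined for this model")
        return float(value)


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability raster in [0, 1] (NaN = nodata)."""

    values: np.ndarray
    geometry: GridGeometry
    species: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")

    def sample(self, x, y) -> np.ndarray:
        row, col = self.geometry.index_of(x, y)
        row = np.clip(row, 0, self.geometry.rows - 1)
        col = np.clip(col, 0, self.geometry.cols - 1)
        return self.values[row, col]

    def valid_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


@dataclass
class EnsembleResult:
    map: SuitabilityMap
    members: list[dict]  # learner, replicate, weight, scores
    weights: np.ndarray
    radius: float
    scores: list[EvalScores] = field(default_factory=list)


def _coord_key(x: np.ndarray, y: np.ndarray) -> pd.Index:
    return pd.Index(zip(np.round(x, 6), np.round(y, 6)))


def build_modelling_table(
    occurrences: pd.DataFrame,
    predictor_table: pd.DataFrame,
    target: str,
    year: int,
    radius: float,
    min_presences: int = 10,
) -> ModellingTable:
    """Assemble presences and target-group backgrounds for one model.

    Presences are the target's presence points for the year; backgrounds
    are the other species' presence points from the same survey,
    deduplicated by location and excluding any location where the target
    itself is present. Species-years with ``<= min_presences`` presences
    raise :class:`TooFewPresencesError` (the pipeline skips them).
    """
    occ = occurrences[occurrences["year"] == year]
    occ = occ[occ.get("presence", 1) == 1]
    pres = occ[occ["species"] == target]
    others = occ[occ["species"] != target]
    if len(pres) <= min_presences:
        raise TooFewPresencesError(target, len(pres), min_presences)

    pres_xy = pres[["x", "y"]].to_numpy()
    pres_keys = set(_coord_key(pres_xy[:, 0], pres_xy[:, 1]))

    bg = others.copy()
    bg["_key"] = _coord_key(bg["x"].to_numpy(), bg["y"].to_numpy())
    bg = bg[~bg["_key"].isin(pres_keys)]
    provenance = bg.groupby("_key")["species"].agg(lambda s: "+".join(sorted(set(s))))
    bg = bg.drop_duplicates("_key")

    cols = tuple(f"{acr}_{int(radius)}" for acr in PREDICTOR_CLASSES)
    missing = [c for c in cols if c not in predictor_table.columns]
    if missing:
        raise ValueError(f"predictor table lacks columns {missing}")
    ptab = predictor_table.copy()
    ptab.index = _coord_key(ptab["x"].to_numpy(), ptab["y"].to_numpy())
    ptab = ptab[~ptab.index.duplicated()]

    def rows_for(xy_keys, response, prov):
        miss = [k for k in xy_keys if k not in ptab.index]
        if miss:
            raise ValueError(f"{len(miss)} points lack predictor rows")
        block = ptab.loc[list(xy_keys), ["x", "y", *cols]].reset_index(drop=True)
        block["response"] = response
        block["provenance"] = prov
        return block

    pres_block = rows_for(list(_coord_key(pres_xy[:, 0], pres_xy[:, 1])), 1, target)
    bg_keys = list(bg["_key"])
    bg_block = rows_for(bg_keys, 0, [provenance[k] for k in bg_keys])
    frame = pd.concat([pres_block, bg_block], ignore_index=True)
    frame = frame.dropna(subset=list(cols)).reset_index(drop=True)
    return ModellingTable(frame, target, year, float(radius), cols)


def make_splits(
    table: ModellingTable, frac: float = 0.7, n_rep: int = 30, seed: int = 0
) -> list[SplitPlan]:
    """Repeated stratified calibration/validation splits (default 70/30 x 30)."""
    y = table.frame["response"].to_numpy()
    strata = [np.flatnonzero(y == v) for v in (0, 1)]
    for s in strata:
        if s.size < 2:
            raise ValueError("each response class needs at least 2 rows to split")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, n_rep + 1):
        cal_parts, val_parts = [], []
        for s in strata:
            perm = rng.permutation(s)
            n_cal = int(round(frac * s.size))
            n_cal = min(max(n_cal, 1), s.size - 1)  # both subsets non-empty
            cal_parts.append(perm[:n_cal])
            val_parts.append(perm[n_cal:])
        plans.append(
            SplitPlan(
                replicate=rep,
                calibration=np.sort(np.concatenate(cal_parts)),
                validation=np.sort(np.concatenate(val_parts)),
                seed=seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Learner registry
# ---------------------------------------------------------------------------


class LogisticLearner:
    """Standardized penalized logistic regression scorer."""

    def __init__(self, C: float = 1.0, max_iter: int = 1000):
        self._model = make_pipeline(
            StandardScaler(), LogisticRegression(C=C, max_iter=max_iter)
        )

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LogisticLearner":
        self._model.fit(x, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(x)[:, 1]

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients on the original predictor scale."""
        scaler = self._model.named_steps["standardscaler"]
        lr = self._model.named_steps["logisticregression"]
        return lr.coef_[0] / scaler.scale_


class SRELearner:
    """Surface range envelope (rectilinear climate-envelope rule).

    Fits per-predictor percentile bounds on the calibration *presences*
    (default 2.5–97.5; ``(0, 100)`` gives the min–max box) and scores 1
    inside the box, 0 outside.
    """

    def __init__(self, percentiles: tuple[float, float] = (2.5, 97.5)):
        self.percentiles = percentiles
        self.low: np.ndarray | None = None
        self.high: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SRELearner":
        pres = x[y == 1]
        if len(pres) == 0:
            raise ConstantResponseError("SRE needs at least one presence")
        self.low = np.percentile(pres, self.percentiles[0], axis=0)
        self.high = np.percentile(pres, self.percentiles[1], axis=0)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        inside = (x >= self.low - 1e-12) & (x <= self.high + 1e-12)
        return inside.all(axis=1).astype(float)


_LEARNERS = {"logistic": LogisticLearner, "sre": SRELearner}


def register_learner(name: str, factory) -> None:
    _LEARNERS[name] = factory


def get_learner(spec):
    """Instantiate a learner from a name or a (name, kwargs) pair."""
    if isinstance(spec, str):
        name, kwargs = spec, {}
    else:
        name, kwargs = spec
    if name not in _LEARNERS:
        raise KeyError(f"unknown learner {name!r}; registered: {sorted(_LEARNERS)}")
    return _LEARNERS[name](**kwargs)


def fit_and_predict(
    learner_spec,
    table: ModellingTable,
    split: SplitPlan,
    stack: PredictorStack,
) -> tuple[np.ndarray, SuitabilityMap]:
    """Fit one learner on a calibration subset; score validation rows and
    every analysis cell of the predictor stack."""
    x, y = table.design()
    y_cal = y[split.calibration]
    if len(np.unique(y_cal)) < 2:
        raise ConstantResponseError(
            f"calibration subset of replicate {split.replicate} has one class"
        )
    learner = get_learner(learner_spec).fit(x[split.calibration], y_cal)
    val_pred = np.clip(learner.predict(x[split.validation]), 0.0, 1.0)

    frame = stack.to_frame()
    cols = [f"{acr}_{int(table.radius)}" for acr in PREDICTOR_CLASSES]
    cell_x = frame[cols].to_numpy(dtype=float)
    valid = ~np.isnan(cell_x).any(axis=1)
    cell_pred = np.full(len(cell_x), np.nan)
    if valid.any():
        cell_pred[valid] = np.clip(learner.predict(cell_x[valid]), 0.0, 1.0)
    smap = SuitabilityMap(
        cell_pred.reshape(stack.geometry.shape), stack.geometry,
        species=table.target, year=table.year,
    )
    return val_pred, smap


def evaluate_model(
    predictions: np.ndarray, truth: np.ndarray, thresholds: np.ndarray | None = None
) -> EvalScores:
    """AUC plus TSS and kappa maximized over a fixed threshold grid."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    auc = float(roc_auc_score(truth, predictions))

    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    pred_pos = predictions[None, :] >= thresholds[:, None]
    tp = (pred_pos & pos[None, :]).sum(axis=1)
    fp = (pred_pos & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    tss = sens + spec - 1.0

    n = n_pos + n_neg
    po = (tp + (n_neg - fp)) / n
    p_yes = (tp + fp) / n
    pe = p_yes * (n_pos / n) + (1 - p_yes) * (n_neg / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)

    i_tss = int(np.argmax(tss))
    i_kap = int(np.argmax(kappa))
    return EvalScores(
        auc=auc,
        tss=float(tss[i_tss]),
        kappa=float(kappa[i_kap]),
        tss_threshold=float(thresholds[i_tss]),
        kappa_threshold=float(thresholds[i_kap]),
    )


def boyce_index(
    presence_predictions: np.ndarray,
    landscape_predictions: np.ndarray,
    n_bins: int = 101,
    window_width: float = 0.1,
) -> float | Undefined:
    """Continuous Boyce index of a projected suitability model.

    A window of width ``window_width`` times the landscape suitability
    range slides across ``n_bins`` overlapping positions; in each window
    the predicted presence frequency is divided by the expected frequency
    under a random distribution (the landscape share), and the score is
    the Spearman rank correlation between window mid-suitability and that
    P/E ratio. Windows with zero expected frequency are dropped. +1 means
    presences concentrate monotonically in high-suitability cells, 0 a
    model no better than random, negative values counter-predictions.
    """
    pres = np.asarray(presence_predictions, dtype=float)
    land = np.asarray(landscape_predictions, dtype=float)
    pres = pres[~np.isnan(pres)]
    land = land[~np.isnan(land)]
    if pres.size < 10:
        raise ValueError("need at least 10 presence predictions")
    if land.size < 100:
        raise ValueError("need a landscape sample of at least 100 predictions")
    lo, hi = float(land.min()), float(land.max())
    if hi - lo <= 0:
        return Undefined("constant landscape predictions")
    width = window_width * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_bins)
    lows = mids - width / 2
    highs = mids + width / 2
    p = ((pres[None, :] >= lows[:, None]) & (pres[None, :] <= highs[:, None])).mean(axis=1)
    e = ((land[None, :] >= lows[:, None]) & (land[None, :] <= highs[:, None])).mean(axis=1)
    keep = e > 0
    if keep.sum() < 3:
        return Undefined("fewer than 3 windows with non-zero expected frequency")
    f_ratio = p[keep] / e[keep]
    if np.allclose(f_ratio, f_ratio[0]):
        return Undefined("constant predicted-to-expected ratio")
    rho = spearmanr(mids[keep], f_ratio).statistic
    return float(rho)


def build_ensemble(
    members: list[tuple[SuitabilityMap, EvalScores]],
    weight_metric: str = "tss",
    quality_floor: float = 0.4,
) -> EnsembleResult:
    """Cell-wise weighted mean of member maps.

    Members whose ``weight_metric`` falls below ``quality_floor`` are
    dropped; weights are proportional to max(metric, 0) among the rest
    (uniform if all retained metrics are <= 0) and normalized to 1.
    """
    if not members:
        raise ValueError("no members supplied")
    retained = [(m, s) for m, s in members if s.metric(weight_metric) >= quality_floor]
    if not retained:
        raise ValueError(
            f"no member reached the quality floor {weight_metric} >= {quality_floor}; "
            "consider relaxing the floor"
        )
    raw = np.array([max(s.metric(weight_metric), 0.0) for _, s in retained])
    if raw.sum() == 0:
        raw = np.ones(len(retained))
    weights = raw / raw.sum()
    stackvals = np.stack([m.values for m, _ in retained])
    combined = np.einsum("k,kij->ij", weights, stackvals)
    first = retained[0][0]
    result_map = SuitabilityMap(combined, first.geometry, first.species, first.year)
    member_meta = [
        {"weight": float(w), "scores": s} for w, (_, s) in zip(weights, retained)
    ]
    return EnsembleResult(
        map=result_map,
        members=member_meta,
        weights=weights,
        radius=np.nan,
        scores=[s for _, s in retained],
    )


def select_best_level(boyce_by_radius: dict[float, float | Undefined]) -> float:
    """Radius with maximal Boyce score; ties go to the smaller radius."""
    if len(boyce_by_radius) < 2:
        raise ValueError("need at least two radii to select among")
    defined = {r: b for r, b in boyce_by_radius.items() if _is_defined(b)}
    if not defined:
        raise ValueError("Boyce score undefined at every radius")
    best = max(sorted(defined), key=lambda r: (defined[r], -r))
    return best


def plan_experiment(
    n_learners: int, n_replicates: int, n_radii: int, n_years: int
) -> int:
    """Single-model fits per species = learners x replicates x radii x years."""
    for name, v in (
        ("n_learners", n_learners),
        ("n_replicates", n_replicates),
        ("n_radii", n_radii),
        ("n_years", n_years),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    return n_learners * n_replicates * n_radii * n_years


# ---------------------------------------------------------------------------
# Convenience orchestration
# ---------------------------------------------------------------------------


def ensemble_for(
    table: ModellingTable,
    stack: PredictorStack,
    learners=("logistic", "sre"),
    n_replicates: int = 30,
    seed: int = 0,
    weight_metric: str = "tss",
    quality_floor: float = 0.4,
) -> EnsembleResult:
    """Fit learners x replicates for one species-year-radius and ensemble.

    Members whose calibration subset degenerates to one class are excluded
    with a note rather than failing the whole ensemble.
    """
    splits = make_splits(table, n_rep=n_replicates, seed=seed)
    members: list[tuple[SuitabilityMap, EvalScores]] = []
    ledger = []
    for spec in learners:
        name = spec if isinstance(spec, str) else spec[0]
        for split in splits:
            try:
                val_pred, smap = fit_and_predict(spec, table, split, stack)
                scores = evaluate_model(
                    val_pred, table.frame["response"].to_numpy()[split.validation]
                )
            except (ConstantResponseError, ValueError) as exc:
                ledger.append(
                    {"learner": name, "replicate": split.replicate, "excluded": str(exc)}
                )
                continue
            members.append((smap, scores))
            ledger.append(
                {
                    "learner": name,
                    "replicate": split.replicate,
                    "auc": scores.auc,
                    "tss": scores.tss,
                    "kappa": scores.kappa,
                }
            )
    result = build_ensemble(members, weight_metric=weight_metric, quality_floor=quality_floor)
    result.radius = table.radius
    result.map.species = table.target
    result.map.year = table.year
    result.members = ledger
    return result


def ensemble_boyce(result: EnsembleResult, presence_x, presence_y) -> float | Undefined:
    """Boyce score of a projected ensemble against presence locations."""
    pres_pred = result.map.sample(presence_x, presence_y)
    return boyce_index(pres_pred, result.map.valid_values())
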