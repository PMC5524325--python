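"""Synthetic landscapes, surveys and protected-area masks.

The monitoring protocol is calibrated on a fire-prone Iberian landscape
mosaic observed at two dates: eight land-cover classes (two forest types,
two shrubland states, meadow/fallow, arable, water, urban), road-based
raptor surveys on a coarse sampling lattice, and three overlapping
protected-area systems (SAC, SPA and their union N2000). This module
generates inputs with exactly that statistical structure so every
downstream stage — classification, focal predictors, suitability
ensembles, thresholds, indices — can be exercised end to end without any
external data:

* spatially autocorrelated categorical class maps (smoothed Gaussian
  fields, weighted argmax) with a per-cell Markov transition from the
  first to the second date; water and urban rows are identity, encoding
  their assumed constancy over the study period;
* multiband reflectance scenes drawn per cell from Gaussian class
  signatures chosen to be spectrally separable (pairwise transformed
  divergence above 1.99);
* occurrence points along straight survey transects whose presence
  probability is a known logistic function of class composition within a
  known species-specific radius — the ground truth for parameter-recovery
  tests;
* grown-region SAC/SPA masks hitting requested coverage fractions, with
  N2000 their cell-wise union.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import NODATA_INT, GridGeometry
from .landcover import LULCMap, SpectralScene
from .predictors import CLASS_ACRONYMS, extract_at_points

__all__ = [
    "PALETTE",
    "LandscapeConfig",
    "SpeciesPreference",
    "SurveyDesign",
    "PAMaskSet",
    "default_landscape_config",
    "default_species_preferences",
    "generate_landscape",
    "generate_pa_masks",
    "generate_occurrences",
    "survey_totals",
]

PALETTE = (
    "deciduous forest",
    "coniferous forest",
    "closed shrubland",
    "open shrubland",
    "meadow/fallow",
    "arable",
    "water",
    "urban",
)

VALID_RADII = (500.0, 1000.0, 2000.0, 5000.0)

# Mean surface reflectance per class over the six reflective bands
# (blue, green, red, NIR, SWIR1, SWIR2) — plausible magnitudes for the
# class spectra, tuned only for mutual separability.
_SIGNATURE_MEANS = {
    "deciduous forest": (0.030, 0.060, 0.040, 0.450, 0.200, 0.090),
    "coniferous forest": (0.025, 0.050, 0.035, 0.300, 0.140, 0.060),
    "closed shrubland": (0.040, 0.070, 0.060, 0.280, 0.220, 0.120),
    "open shrubland": (0.060, 0.090, 0.100, 0.220, 0.260, 0.180),
    "meadow/fallow": (0.050, 0.090, 0.070, 0.400, 0.280, 0.140),
    "arable": (0.080, 0.120, 0.140, 0.300, 0.320, 0.240),
    "water": (0.050, 0.040, 0.030, 0.020, 0.010, 0.005),
    "urban": (0.120, 0.140, 0.160, 0.200, 0.260, 0.280),
}
_SIGNATURE_SD = 0.01

_DEFAULT_WEIGHTS = (0.20, 0.15, 0.22, 0.13, 0.13, 0.12, 0.03, 0.02)
_DEFAULT_RANGES = (400.0, 400.0, 300.0, 300.0, 250.0, 250.0, 300.0, 200.0)

# Default t1 -> t2 class transitions: fire turns closed shrubland open,
# vegetation regrows, some conifer stands are clear-cut; water and urban
# rows are identity (assumed constant over the period).
_DEFAULT_TRANSITION = (
    (0.96, 0.00, 0.02, 0.02, 0.00, 0.00, 0.0, 0.0),
    (0.00, 0.92, 0.02, 0.05, 0.00, 0.01, 0.0, 0.0),
    (0.02, 0.02, 0.80, 0.12, 0.03, 0.01, 0.0, 0.0),
    (0.01, 0.02, 0.25, 0.70, 0.01, 0.01, 0.0, 0.0),
    (0.01, 0.00, 0.05, 0.02, 0.85, 0.07, 0.0, 0.0),
    (0.00, 0.00, 0.02, 0.01, 0.10, 0.87, 0.0, 0.0),
    (0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.0, 0.0),
    (0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.0, 1.0),
)


@dataclass
class LandscapeConfig:
    """Full recipe for a two-date synthetic landscape."""

    rows: int = 200
    cols: int = 200
    cell_size: float = 50.0
    class_labels: tuple[str, ...] = PALETTE
    weights: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_WEIGHTS))
    autocorr_ranges: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_RANGES))
    signature_means: np.ndarray = field(
        default_factory=lambda: np.array([_SIGNATURE_MEANS[c] for c in PALETTE])
    )
    signature_covs: np.ndarray = field(
        default_factory=lambda: np.tile(
            np.eye(6) * _SIGNATURE_SD**2, (len(PALETTE), 1, 1)
        )
    )
    transition: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_TRANSITION))
    n_bands: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.class_labels)
        self.weights = np.asarray(self.weights, dtype=float)
        self.autocorr_ranges = np.asarray(self.autocorr_ranges, dtype=float)
        self.signature_means = np.asarray(self.signature_means, dtype=float)
        self.signature_covs = np.asarray(self.signature_covs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.rows < 8 or self.cols < 8:
            raise ValueError("degenerate grid: need at least 8 x 8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.weights.shape != (k,) or self.weights.sum() <= 0 or (self.weights < 0).any():
            raise ValueError("weights must be non-negative with positive sum")
        if self.transition.shape != (k, k) or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if self.signature_means.shape != (k, self.n_bands):
            raise ValueError("signature means must be (n_classes, n_bands)")
        if self.signature_covs.shape != (k, self.n_bands, self.n_bands):
            raise ValueError("signature covariances must be (n_classes, B, B)")
        for idx, cov in enumerate(self.signature_covs):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance for class {self.class_labels[idx]!r} not symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance for class {self.class_labels[idx]!r} is not positive-definite"
                ) from exc

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(0.0, self.rows * self.cell_size, self.cell_size, self.rows, self.cols)


@dataclass(frozen=True)
class SpeciesPreference:
    """Known species–habitat association used to generate occurrences.

    ``coefficients`` maps class acronyms (e.g. ``CShr``) to log-odds per
    percentage point of cover within ``radius`` meters of a point.
    """

    acronym: str
    intercept: float
    coefficients: dict[str, float]
    radius: float
    expected_presences: float = 20.0

    def __post_init__(self) -> None:
        if self.radius not in VALID_RADII:
            raise ValueError(f"radius must be one of {VALID_RADII}")


@dataclass(frozen=True)
class SurveyDesign:
    """Road-survey emulation: straight transects across sampled lattice cells."""

    sampling_cell_size: float = 10_000.0
    n_cells: int = 34
    route_length_km: float = 40.0
    point_spacing: float = 500.0

    def __post_init__(self) -> None:
        if min(self.sampling_cell_size, self.route_length_km, self.point_spacing) <= 0:
            raise ValueError("all survey design fields must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class PAMaskSet:
    """Boolean SAC/SPA/N2000 masks on the analysis grid (N2000 = union)."""

    sac: np.ndarray
    spa: np.ndarray
    geometry: GridGeometry
    n2000: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sac = np.asarray(self.sac, dtype=bool)
        self.spa = np.asarray(self.spa, dtype=bool)
        if self.sac.shape != self.geometry.shape or self.spa.shape != self.geometry.shape:
            raise ValueError("mask shapes must match geometry")
        union = self.sac | self.spa
        if self.n2000 is None:
            self.n2000 = union
        elif not np.array_equal(np.asarray(self.n2000, dtype=bool), union):
            raise ValueError("N2000 mask must equal the cell-wise union of SAC and SPA")
        if not self.sac.any() or not self.spa.any():
            raise ValueError("each system must have positive surface")

    def mask(self, system: str) -> np.ndarray:
        return {"SAC": self.sac, "SPA": self.spa, "N2000": self.n2000}[system]

    def surface_ha(self, system: str) -> float:
        return float(self.mask(system).sum()) * self.geometry.cell_area_ha

    def coverage(self, system: str) -> float:
        return float(self.mask(system).mean())


def default_landscape_config(rows: int = 200, cols: int = 200, cell_size: float = 50.0,
                             seed: int = 0) -> LandscapeConfig:
    """The default two-date landscape recipe used throughout the tests."""
    return LandscapeConfig(rows=rows, cols=cols, cell_size=cell_size, seed=seed)


def default_species_preferences() -> list[SpeciesPreference]:
    """Seven species spanning open-habitat specialists to forest species.

    Acronyms follow the survey convention; intercepts are set so expected
    presence counts per year land in the tens-to-low-hundreds range, and
    each species responds to composition at its own characteristic radius.
    """
    return [
        SpeciesPreference("PAPI", -4.0, {"DeFo": 0.07, "CoFo": 0.03}, 2000.0, 15),
        SpeciesPreference("MMIG", -3.5, {"DeFo": 0.04, "Med": 0.04}, 500.0, 28),
        SpeciesPreference("CGAL", -3.0, {"OShr": 0.04, "CShr": 0.02}, 1000.0, 22),
        SpeciesPreference("CPYG", -4.5, {"CShr": 0.09}, 500.0, 40),
        SpeciesPreference("BBUT", -1.5, {"DeFo": 0.02, "Med": 0.02}, 500.0, 150),
        SpeciesPreference("HPEN", -4.5, {"DeFo": 0.06, "CoFo": 0.04}, 1000.0, 10),
        SpeciesPreference("FTIN", -4.0, {"Med": 0.05, "ArL": 0.05}, 500.0, 38),
    ]


def _autocorrelated_class_map(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Weighted argmax over per-class smoothed Gaussian fields.

    Per-class offsets are calibrated on the realized fields so class
    proportions track the configured weights.
    """
    k = len(config.class_labels)
    shape = (config.rows, config.cols)
    fields = np.empty((k,) + shape)
    for c in range(k):
        sigma = max(config.autocorr_ranges[c] / config.cell_size, 0.5)
        f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
        sd = f.std()
        fields[c] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    weights = config.weights / config.weights.sum()
    offsets = np.where(weights > 0, 0.0, -np.inf)
    eps = 1e-12
    n = config.rows * config.cols
    for _ in range(300):
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
        props = np.bincount(labels.ravel(), minlength=k) / n
        err = props - weights
        if np.abs(err).max() < 0.002:
            break
        step = 0.5 * (np.log(weights + eps) - np.log(props + eps))
        offsets = np.where(np.isfinite(offsets), offsets + step, offsets)
    return labels.astype(np.int16)


def _apply_transition(labels: np.ndarray, transition: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(transition, axis=1)
    u = rng.random(labels.shape)
    return (u[..., None] > cum[labels]).sum(axis=-1).astype(np.int16)


def _draw_scene(labels: np.ndarray, config: LandscapeConfig,
                rng: np.random.Generator) -> SpectralScene:
    bands = np.empty((config.n_bands,) + labels.shape)
    flat = bands.reshape(config.n_bands, -1)
    lab_flat = labels.ravel()
    for c in range(len(config.class_labels)):
        idx = np.flatnonzero(lab_flat == c)
        if idx.size == 0:
            continue
        samples = rng.multivariate_normal(
            config.signature_means[c], config.signature_covs[c], size=idx.size,
            method="cholesky",
        )
        flat[:, idx] = samples.T
    names = ("blue", "green", "red", "nir", "swir1", "swir2")[: config.n_bands]
    return SpectralScene(bands, config.geometry, band_names=names)


def generate_landscape(
    config: LandscapeConfig, seed: int | None = None
) -> tuple[SpectralScene, SpectralScene, LULCMap, LULCMap]:
    """Generate (scene@t1, scene@t2, truth@t1, truth@t2).

    The t1 class map is a spatially autocorrelated categorical field; the
    t2 map applies the class-transition matrix independently per cell;
    scenes are drawn per cell from the class spectral signatures.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels_t1 = _autocorrelated_class_map(config, rng)
    labels_t2 = _apply_transition(labels_t1, config.transition, rng)
    scene_t1 = _draw_scene(labels_t1, config, rng)
    scene_t2 = _draw_scene(labels_t2, config, rng)
    truth_t1 = LULCMap(labels_t1, config.class_labels, config.geometry)
    truth_t2 = LULCMap(labels_t2, config.class_labels, config.geometry)
    return scene_t1, scene_t2, truth_t1, truth_t2


_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _grow_region(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target: int,
    grown: np.ndarray,
    start_from: np.ndarray | None = None,
) -> None:
    """Randomly grow ``grown`` by ``target`` cells within ``allowed``.

    Growth proceeds by repeatedly annexing a random frontier cell
    (4-neighborhood); exhausted frontiers are re-seeded at a random
    allowed cell, so the exact target count is always reached when
    feasible. Mutates ``grown`` in place.
    """
    rows, cols = allowed.shape
    frontier: list[tuple[int, int]] = []

    def push_neighbors(i: int, j: int) -> None:
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < rows and 0 <= nj < cols and allowed[ni, nj] and not grown[ni, nj]:
                frontier.append((ni, nj))

    if start_from is not None:
        for i, j in zip(*np.nonzero(start_from)):
            push_neighbors(int(i), int(j))
    added = 0
    capacity = int((allowed & ~grown).sum())
    if target > capacity:
        raise ValueError("infeasible growth target for the allowed region")
    while added < target:
        if not frontier:
            candidates = np.flatnonzero((allowed & ~grown).ravel())
            pick = int(candidates[rng.integers(candidates.size)])
            i, j = divmod(pick, cols)
        else:
            idx = int(rng.integers(len(frontier)))
            frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
            i, j = frontier.pop()
            if grown[i, j] or not allowed[i, j]:
                continue
        grown[i, j] = True
        added += 1
        push_neighbors(i, j)


def generate_pa_masks(
    config: LandscapeConfig | GridGeometry,
    sac_frac: float = 0.166,
    spa_frac: float = 0.083,
    overlap_frac: float = 0.07,
    seed: int = 0,
) -> PAMaskSet:
    """Grow SAC and SPA masks with requested coverages and mutual overlap.

    Realized coverage matches each requested fraction to the cell-rounding
    limit (well within one percentage point); N2000 is the union, so with
    the default fractions its coverage is sac + spa - overlap ~ 17.9%.
    """
    geometry = config.geometry if isinstance(config, LandscapeConfig) else config
    for name, frac in (("sac_frac", sac_frac), ("spa_frac", spa_frac)):
        if not 0 < frac < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if not 0 <= overlap_frac <= min(sac_frac, spa_frac):
        raise ValueError("overlap_frac must be in [0, min(sac_frac, spa_frac)]")
    if sac_frac + spa_frac - overlap_frac > 1:
        raise ValueError("infeasible fractions: sac + spa - overlap exceeds 1")
    rng = np.random.default_rng(seed)
    n = geometry.rows * geometry.cols
    shape = geometry.shape
    everywhere = np.ones(shape, dtype=bool)

    sac = np.zeros(shape, dtype=bool)
    _grow_region(rng, everywhere, max(int(round(sac_frac * n)), 1), sac)

    spa = np.zeros(shape, dtype=bool)
    overlap_target = int(round(overlap_frac * n))
    if overlap_target > 0:
        _grow_region(rng, sac, overlap_target, spa)
    outside_target = max(int(round(spa_frac * n)) - overlap_target, 0)
    if outside_target > 0:
        _grow_region(rng, ~sac, outside_target, spa,
                     start_from=spa if overlap_target else None)
    if not spa.any():  # overlap == spa_frac rounding to zero cells
        _grow_region(rng, sac, 1, spa)
    return PAMaskSet(sac=sac, spa=spa, geometry=geometry)


def _transect_points(geometry: GridGeometry, design: SurveyDesign,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Candidate observation points along straight east-west transects.

    Each sampled lattice cell receives enough full-width passes to cover
    the configured route length, with points every ``point_spacing`` m.
    """
    xmin, ymin, xmax, ymax = geometry.bounds
    size = design.sampling_cell_size
    nx = max(int((xmax - xmin) // size), 1)
    ny = max(int((ymax - ymin) // size), 1)
    total = nx * ny
    chosen = rng.choice(total, size=min(design.n_cells, total), replace=False)
    cell_w = min(size, xmax - xmin)
    n_passes = max(int(round(design.route_length_km * 1000.0 / cell_w)), 1)
    xs, ys = [], []
    for c in np.sort(chosen):
        cy, cx = divmod(int(c), nx)
        x0 = xmin + cx * size
        y0 = ymax - cy * size
        y1 = max(y0 - size, ymin)
        lane_y = y1 + (rng.random(n_passes)) * (y0 - y1)
        along = np.arange(design.point_spacing / 2, cell_w, design.point_spacing)
        for ly in lane_y:
            xs.append(x0 + along)
            ys.append(np.full(along.size, ly))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    keep = geometry.contains(x, y)
    return pd.DataFrame({"x": x[keep], "y": y[keep]})


def generate_occurrences(
    truth: LULCMap,
    prefs: list[SpeciesPreference],
    design: SurveyDesign,
    year: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a road survey over a known landscape.

    Candidate points are laid along transects in sampled lattice cells;
    each species' presence at each point is Bernoulli with
    ``logit p = intercept + sum_c coeff_c * (% class c within its radius)``.
    Returns a long table with columns species, x, y, year, presence
    (attrs carry warnings for species whose expected presences < 1).
    """
    if not prefs:
        raise ValueError("need at least one species preference")
    rng = np.random.default_rng(seed)
    points = _transect_points(truth.geometry, design, rng)
    radii = sorted({p.radius for p in prefs})
    comp = extract_at_points(truth, points, radii=radii) if len(points) else None
    frames = []
    warnings: list[str] = []
    for pref in prefs:
        if comp is None or not len(points):
            frames.append(pd.DataFrame(columns=["species", "x", "y", "year", "presence"]))
            continue
        logit = np.full(len(points), pref.intercept)
        for acr, coef in pref.coefficients.items():
            col = f"{acr}_{int(pref.radius)}"
            logit = logit + coef * np.nan_to_num(comp[col].to_numpy(), nan=0.0)
        prob = expit(logit)
        expected = float(prob.sum())
        if expected < 1.0:
            warnings.append(
                f"{pref.acronym}: expected presences {expected:.2f} < 1 in year {year}"
            )
        presence = (rng.random(len(points)) < prob).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "species": pref.acronym,
                    "x": points["x"].to_numpy(),
                    "y": points["y"].to_numpy(),
                    "year": year,
                    "presence": presence,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.attrs["warnings"] = warnings
    table.attrs["n_candidates"] = len(points)
    return table


def survey_totals(design: SurveyDesign, per_year_counts: dict[int, int]) -> dict[str, float]:
    """Survey bookkeeping: total route length and pooled observations."""
    if any(v < 0 for v in per_year_counts.values()):
        raise ValueError("observation counts must be >= 0")
    return {
        "total_route_km": design.n_cells * design.route_length_km,
        "total_observations": float(sum(per_year_counts.values())),
    }
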