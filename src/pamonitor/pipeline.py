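"""End-to-end orchestration: simulate → classify → predict → assess.

`run_all` executes the whole monitoring protocol on a synthetic study
region: generate a two-date landscape and survey, classify the scenes into
land-cover maps, derive multi-scale composition predictors from the
classified maps, fit per-species suitability ensembles at each candidate
radius, pick the best radius by the Boyce score of the projected
ensembles (averaged over the two dates), binarize into SH/HSH, and compile
the protected-area assessment report. The run is a pure function of
(config, seed): seeds for every stochastic stage are spawned from the one
master seed in a fixed order, and the serialized report is byte-identical
across repeated runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import indices, landcover, predictors, sdm, synthdata, thresholds

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

logger = logging.getLogger(__name__)

#: Conservation status of the seven surveyed species (Annex I of the
#: Birds Directive; SPEC category), as used for threat weighting.
DEFAULT_STATUSES = {
    "PAPI": (True, "NonSPEC"),
    "MMIG": (True, "SPEC3"),
    "CGAL": (True, "SPEC3"),
    "CPYG": (True, "NonSPEC"),
    "BBUT": (False, "NonSPEC"),
    "HPEN": (True, "SPEC3"),
    "FTIN": (False, "SPEC3"),
}


@dataclass
class PipelineConfig:
    """Study conditions for a full synthetic run."""

    rows: int = 200
    cols: int = 200
    cell_size: float = 50.0
    grain: float = 500.0
    years: tuple[int, int] = (2001, 2014)
    radii: tuple[float, ...] = (500.0, 1000.0, 2000.0)
    learners: tuple[str, ...] = ("logistic", "sre")
    n_replicates: int = 30
    min_presences: int = 10
    pooled_presence_filter: bool = False
    sh_percentile: float = 10.0
    quality_floor: float = 0.4
    weight_metric: str = "tss"
    classifier: str = "max_likelihood"
    training_cells_per_class: int = 60
    validation_cells_per_class: int = 40
    sac_frac: float = 0.166
    spa_frac: float = 0.083
    overlap_frac: float = 0.07
    sampling_cell_size: float = 2000.0
    n_survey_cells: int = 25
    route_length_km: float = 8.0
    point_spacing: float = 500.0
    statuses: dict = field(default_factory=lambda: dict(DEFAULT_STATUSES))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    report: indices.AssessmentReport
    accuracy: dict[int, landcover.ConfusionMatrix]
    separability_flags: list
    best_radius: dict[str, float]
    ensemble_scores: dict  # (species, year, radius) -> {"boyce":..., mean member metrics}
    hsh_masks: dict
    sh_masks: dict
    pa: synthdata.PAMaskSet
    occurrences: dict[int, "object"]
    survey: dict[str, float]
    skipped_species: list[str]


def _training_cells(truth: landcover.LULCMap, n_per_class: int, rng) -> dict[str, np.ndarray]:
    cells = {}
    for cid, label in enumerate(truth.palette):
        idx = np.argwhere(truth.data == cid)
        if len(idx) < n_per_class:
            raise ValueError(f"class {label!r} has only {len(idx)} cells on the truth map")
        pick = rng.choice(len(idx), size=n_per_class, replace=False)
        cells[label] = idx[pick]
    return cells


def run_all(config: PipelineConfig | None = None, seed: int = 0) -> PipelineResult:
    """Run the full monitoring protocol on a synthetic study region."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    (s_land, s_train, s_pa, s_occ1, s_occ2, s_sdm, _, _) = seeds

    # 1. synthetic landscape at two dates
    land_cfg = synthdata.default_landscape_config(
        rows=config.rows, cols=config.cols, cell_size=config.cell_size, seed=s_land
    )
    scene1, scene2, truth1, truth2 = synthdata.generate_landscape(land_cfg)

    # 2. supervised classification of both scenes; accuracy on held-out cells
    rng_train = np.random.default_rng(s_train)
    lulc: dict[int, landcover.LULCMap] = {}
    accuracy: dict[int, landcover.ConfusionMatrix] = {}
    sep_flags: list = []
    for year, scene, truth in (
        (config.years[0], scene1, truth1),
        (config.years[1], scene2, truth2),
    ):
        train = _training_cells(truth, config.training_cells_per_class, rng_train)
        val = _training_cells(truth, config.validation_cells_per_class, rng_train)
        sigs = landcover.fit_signatures(scene, train)
        sep_flags.extend(
            (year, a, b, td) for a, b, td in landcover.screen_separability(sigs)
        )
        lulc[year] = landcover.classify_scene(scene, sigs, config.classifier)
        ref_cells = np.concatenate(list(val.values()))
        ref_labels = np.concatenate(
            [np.full(len(v), cid) for cid, v in enumerate(val.values())]
        )
        accuracy[year] = landcover.assess_accuracy(lulc[year], ref_cells, ref_labels)

    # 3. surveys over the true landscape at both dates
    design = synthdata.SurveyDesign(
        sampling_cell_size=config.sampling_cell_size,
        n_cells=config.n_survey_cells,
        route_length_km=config.route_length_km,
        point_spacing=config.point_spacing,
    )
    prefs = synthdata.default_species_preferences()
    truths = {config.years[0]: truth1, config.years[1]: truth2}
    occurrences = {
        config.years[0]: synthdata.generate_occurrences(
            truth1, prefs, design, config.years[0], seed=s_occ1
        ),
        config.years[1]: synthdata.generate_occurrences(
            truth2, prefs, design, config.years[1], seed=s_occ2
        ),
    }
    counts = {
        y: int(occ["presence"].sum()) for y, occ in occurrences.items()
    }
    survey = synthdata.survey_totals(design, counts)

    # 4. predictors from the classified maps: point tables and stacks
    tables: dict[int, "object"] = {}
    stacks: dict[tuple[int, float], predictors.PredictorStack] = {}
    for year in config.years:
        pts = occurrences[year][["x", "y"]].drop_duplicates().reset_index(drop=True)
        tables[year] = predictors.extract_at_points(lulc[year], pts, radii=config.radii)
        for radius in config.radii:
            stacks[(year, radius)] = predictors.focal_composition(
                lulc[year], radius, config.grain
            )

    # 5. per-species modelling: radius selection by mean ensemble Boyce
    species_list = [p.acronym for p in prefs if p.acronym in config.statuses]
    statuses = {
        s: indices.threat_status(s, *config.statuses[s]) for s in species_list
    }
    rng_sdm = np.random.default_rng(s_sdm)
    sdm_seeds = {
        (s, y, r): int(rng_sdm.integers(2**31))
        for s in species_list
        for y in config.years
        for r in config.radii
    }
    best_radius: dict[str, float] = {}
    ensemble_scores: dict = {}
    hsh_masks: dict = {}
    sh_masks: dict = {}
    skipped: list[str] = []
    for sp in species_list:
        if config.pooled_presence_filter:
            pooled = sum(
                int(
                    (
                        (occurrences[y]["species"] == sp)
                        & (occurrences[y]["presence"] == 1)
                    ).sum()
                )
                for y in config.years
            )
            if pooled <= config.min_presences:
                skipped.append(sp)
                logger.info("skipping %s: pooled presences %d", sp, pooled)
                continue
        ensembles: dict[tuple[int, float], sdm.EnsembleResult] = {}
        boyce_by_radius: dict[float, float] = {}
        try:
            for radius in config.radii:
                per_year_boyce = []
                for year in config.years:
                    per_year_filter = (
                        0 if config.pooled_presence_filter else config.min_presences
                    )
                    table = sdm.build_modelling_table(
                        occurrences[year],
                        tables[year],
                        sp,
                        year,
                        radius,
                        min_presences=per_year_filter,
                    )
                    try:
                        result = sdm.ensemble_for(
                            table,
                            stacks[(year, radius)],
                            learners=config.learners,
                            n_replicates=config.n_replicates,
                            seed=sdm_seeds[(sp, year, radius)],
                            weight_metric=config.weight_metric,
                            quality_floor=config.quality_floor,
                        )
                    except ValueError:
                        logger.warning(
                            "%s %d r=%g: no member above floor, retrying with floor 0",
                            sp, year, radius,
                        )
                        result = sdm.ensemble_for(
                            table,
                            stacks[(year, radius)],
                            learners=config.learners,
                            n_replicates=config.n_replicates,
                            seed=sdm_seeds[(sp, year, radius)],
                            weight_metric=config.weight_metric,
                            quality_floor=0.0,
                        )
                    ensembles[(year, radius)] = result
                    occ = occurrences[year]
                    mask = (occ["species"] == sp) & (occ["presence"] == 1)
                    b = sdm.ensemble_boyce(
                        result, occ.loc[mask, "x"].to_numpy(), occ.loc[mask, "y"].to_numpy()
                    )
                    member_metrics = [
                        m for m in result.members if "auc" in m
                    ]
                    ensemble_scores[(sp, year, radius)] = {
                        "boyce": b if sdm._is_defined(b) else None,
                        "auc": float(np.mean([m["auc"] for m in member_metrics])),
                        "tss": float(np.mean([m["tss"] for m in member_metrics])),
                        "kappa": float(np.mean([m["kappa"] for m in member_metrics])),
                    }
                    if sdm._is_defined(b):
                        per_year_boyce.append(b)
                boyce_by_radius[radius] = (
                    float(np.mean(per_year_boyce))
                    if per_year_boyce
                    else sdm.Undefined("no defined Boyce score at this radius")
                )
        except sdm.TooFewPresencesError as exc:
            skipped.append(sp)
            logger.info("skipping %s: %s", sp, exc)
            continue
        best = sdm.select_best_level(boyce_by_radius)
        best_radius[sp] = best

        # 6. two-level thresholding at the selected radius
        for year in config.years:
            result = ensembles[(year, best)]
            occ = occurrences[year]
            mask = (occ["species"] == sp) & (occ["presence"] == 1)
            pres_vals = result.map.sample(
                occ.loc[mask, "x"].to_numpy(), occ.loc[mask, "y"].to_numpy()
            )
            sh = thresholds.suitable_habitat(
                result.map, pres_vals, percentile=config.sh_percentile
            )
            hsh = thresholds.high_suitability(result.map, sh)
            sh_masks[(sp, year)] = sh
            hsh_masks[(sp, year)] = hsh

    # 7. protected-area systems on the analysis grid and final report
    coarse = truth1.geometry.coarsen(config.grain)
    pa = synthdata.generate_pa_masks(
        coarse, config.sac_frac, config.spa_frac, config.overlap_frac, seed=s_pa
    )
    kept_statuses = {s: st for s, st in statuses.items() if s not in skipped}
    report = indices.compile_report(
        hsh_masks, kept_statuses, pa,
        config=config.to_dict(), years=config.years, seed=seed,
    )
    return PipelineResult(
        report=report,
        accuracy=accuracy,
        separability_flags=sep_flags,
        best_radius=best_radius,
        ensemble_scores=ensemble_scores,
        hsh_masks=hsh_masks,
        sh_masks=sh_masks,
        pa=pa,
        occurrences=occurrences,
        survey=survey,
        skipped_species=skipped,
    )
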