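"""Protected-area indices: representativeness, efficiency, effectiveness.

Given a species' high-suitability habitat (HSH) at two dates and a
protected-area system mask, three gap-analysis indices are computed on the
0–100% scale:

* **representativeness** — share of the species' total HSH captured by
  the system: 100 * area(HSH ∩ system) / area(HSH);
* **efficiency** — protection delivered per unit protected area:
  100 * area(HSH ∩ system) / area(system), with the reciprocal reported
  as hectares of protected land per hectare of habitat protected;
* **effectiveness** — temporal retention of protected habitat:
  100 * area(HSH_t2 ∩ system) / area(HSH_t1 ∩ system); values above 100
  mean habitat gain inside the system.

Per-species values are aggregated across the species set with weights
given by threat status T = Annex × SPEC, where inclusion in Annex I of
the Birds Directive or in a SPEC (Species of European Conservation
Concern) category each contribute a factor 2 (else 1), so T ∈ {1, 2, 4}.

Numerators are clipped to the system mask (``clip_to_system``, default
true): efficiency reads as protection per unit area only when the habitat
counted actually lies inside the system.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sdm import Undefined, _is_defined
from .synthdata import PAMaskSet
from .thresholds import HabitatMask

__all__ = [
    "SpeciesStatus",
    "IndexRecord",
    "AssessmentReport",
    "threat_status",
    "area_of",
    "effectiveness",
    "efficiency",
    "representativeness",
    "weighted_index",
    "hsh_change",
    "compile_report",
]

SYSTEMS = ("N2000", "SAC", "SPA")


@dataclass(frozen=True)
class SpeciesStatus:
    """European conservation status of one species and its threat weight."""

    acronym: str
    annex_i: bool
    spec_category: str  # "SPEC3" or "NonSPEC" (other SPEC levels weigh 2)

    @property
    def T(self) -> int:
        annex = 2 if self.annex_i else 1
        spec = 2 if self.spec_category != "NonSPEC" else 1
        return annex * spec


def threat_status(acronym: str, annex_i: bool, spec_category: str) -> SpeciesStatus:
    """Threat weight T = Annex x SPEC; each inclusion doubles the weight."""
    if not isinstance(spec_category, str) or not spec_category:
        raise ValueError("spec_category must be a non-empty string")
    normalized = spec_category.replace("-", "").replace(" ", "")
    if normalized.lower() in ("nonspec", "nonspecies"):
        normalized = "NonSPEC"
    elif normalized.upper().startswith("SPEC"):
        if normalized.upper() not in ("SPEC3",):
            logging.getLogger(__name__).warning(
                "SPEC category %r mapped to weight 2 (any SPEC listing counts)",
                spec_category,
            )
        normalized = normalized.upper()
    else:
        raise ValueError(f"unknown SPEC category {spec_category!r}")
    return SpeciesStatus(acronym, bool(annex_i), normalized)


def _as_bool_array(mask) -> np.ndarray:
    if isinstance(mask, HabitatMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def _geometry_of(mask):
    return mask.geometry if hasattr(mask, "geometry") else None


def area_of(mask, region=None, *, geometry=None) -> float:
    """Area in hectares of true cells (optionally within ``region``)."""
    data = _as_bool_array(mask)
    geom = geometry or _geometry_of(mask)
    if geom is None:
        raise ValueError("geometry required (pass a HabitatMask or geometry=)")
    if data.shape != geom.shape:
        raise ValueError("mask shape does not match geometry")
    if region is not None:
        reg = _as_bool_array(region)
        if reg.shape != data.shape:
            raise ValueError("region grid does not match mask grid")
        data = data & reg
    return float(data.sum()) * geom.cell_area_ha


def effectiveness(hsh_t1, hsh_t2, system, *, geometry=None) -> float | Undefined:
    """100 * area(HSH_t2 within system) / area(HSH_t1 within system)."""
    a1 = area_of(hsh_t1, system, geometry=geometry)
    a2 = area_of(hsh_t2, system, geometry=geometry)
    if a1 == 0:
        return Undefined("no protected HSH at t1")
    return 100.0 * a2 / a1


def efficiency(hsh, system, *, geometry=None) -> tuple[float, float | Undefined]:
    """(percent of the system that is HSH, reciprocal ha-per-ha cost).

    A 0.53 habitat fraction inside a system means ~1.9 hectares protected
    per hectare of habitat; 25% efficiency means 4 ha per ha.
    """
    sys_area = area_of(system, geometry=geometry or _geometry_of(hsh))
    if sys_area == 0:
        raise ValueError("system surface must be > 0")
    hsh_area = area_of(hsh, system, geometry=geometry)
    pct = 100.0 * hsh_area / sys_area
    reciprocal = sys_area / hsh_area if hsh_area > 0 else Undefined("no HSH in system")
    return pct, reciprocal


def representativeness(hsh, system, *, geometry=None) -> float | Undefined:
    """100 * area(HSH within system) / total HSH area."""
    total = area_of(hsh, geometry=geometry)
    if total == 0:
        return Undefined("species has no HSH")
    return 100.0 * area_of(hsh, system, geometry=geometry) / total


def weighted_index(
    values: dict[str, float], statuses: dict[str, SpeciesStatus]
) -> float:
    """Threat-weighted mean: sum(value_i * T_i) / sum(T_i).

    Species with undefined values must be dropped by the caller before
    aggregation (compile_report logs them).
    """
    common = [s for s in values if s in statuses and _is_defined(values[s])]
    if not common:
        raise ValueError("no species with both a value and a status")
    t = np.array([statuses[s].T for s in common], dtype=float)
    v = np.array([values[s] for s in common], dtype=float)
    return float((v * t).sum() / t.sum())


def hsh_change(hsh_t1, hsh_t2, region=None, *, geometry=None) -> float | Undefined:
    """Percent change of HSH area between dates within an optional region."""
    a1 = area_of(hsh_t1, region, geometry=geometry)
    a2 = area_of(hsh_t2, region, geometry=geometry)
    if a1 == 0:
        return Undefined("no HSH at t1 in region")
    return 100.0 * (a2 - a1) / a1


@dataclass
class IndexRecord:
    """All indices for one species x protected-area system."""

    species: str
    system: str
    representativeness_t1: float | Undefined
    representativeness_t2: float | Undefined
    efficiency_t1: float
    efficiency_t2: float
    effectiveness: float | Undefined
    hsh_change_study_area: float | Undefined
    hsh_change_in_system: float | Undefined


def _round(value, nd=6):
    if not _is_defined(value):
        return None
    return round(float(value), nd)


@dataclass
class AssessmentReport:
    """Per-species index records plus threat-weighted system aggregates."""

    records: list[IndexRecord]
    weighted: dict[str, dict[str, float]]  # system -> index -> value
    statuses: dict[str, SpeciesStatus]
    config_hash: str
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: species, system, index, value."""
        rows = []
        for rec in self.records:
            for name in (
                "representativeness_t1",
                "representativeness_t2",
                "efficiency_t1",
                "efficiency_t2",
                "effectiveness",
                "hsh_change_study_area",
                "hsh_change_in_system",
            ):
                rows.append(
                    {
                        "species": rec.species,
                        "system": rec.system,
                        "index": name,
                        "value": _round(getattr(rec, name)),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Deterministic serialization (sorted keys, fixed precision)."""
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "statuses": {
                s: {"annex_i": st.annex_i, "spec": st.spec_category, "T": st.T}
                for s, st in sorted(self.statuses.items())
            },
            "records": [
                {
                    "species": r.species,
                    "system": r.system,
                    "representativeness_t1": _round(r.representativeness_t1),
                    "representativeness_t2": _round(r.representativeness_t2),
                    "efficiency_t1": _round(r.efficiency_t1),
                    "efficiency_t2": _round(r.efficiency_t2),
                    "effectiveness": _round(r.effectiveness),
                    "hsh_change_study_area": _round(r.hsh_change_study_area),
                    "hsh_change_in_system": _round(r.hsh_change_in_system),
                }
                for r in sorted(self.records, key=lambda r: (r.species, r.system))
            ],
            "weighted": {
                sys: {k: _round(v) for k, v in sorted(vals.items())}
                for sys, vals in sorted(self.weighted.items())
            },
            "notes": sorted(self.notes),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def config_digest(config) -> str:
    """Stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def compile_report(
    hsh_masks: dict[tuple[str, int], HabitatMask],
    statuses: dict[str, SpeciesStatus],
    pa: PAMaskSet,
    config: dict | None = None,
    years: tuple[int, int] | None = None,
    seed: int | None = None,
) -> AssessmentReport:
    """Assemble the full index grid and threat-weighted aggregates.

    ``hsh_masks`` maps (species, year) to the species' HSH mask; both
    years must be present for every species with a status. Weighted
    representativeness and efficiency average the two dates (the indices
    exist per date); weighted effectiveness is inherently two-date.
    Species with undefined values are dropped from the corresponding
    aggregate with a note.
    """
    species = sorted(statuses)
    if years is None:
        yrs = sorted({y for _, y in hsh_masks})
        if len(yrs) != 2:
            raise ValueError(f"expected exactly two years in masks, got {yrs}")
        years = (yrs[0], yrs[1])
    t1, t2 = years
    gaps = [
        (s, y) for s in species for y in years if (s, y) not in hsh_masks
    ]
    if gaps:
        raise ValueError(f"missing HSH masks for species-years: {gaps}")

    notes: list[str] = []
    records: list[IndexRecord] = []
    per_species: dict[str, dict[str, dict[str, float | Undefined]]] = {
        sys: {"representativeness": {}, "efficiency": {}, "effectiveness": {}}
        for sys in SYSTEMS
    }
    for s in species:
        m1, m2 = hsh_masks[(s, t1)], hsh_masks[(s, t2)]
        change_study = hsh_change(m1, m2)
        for sys in SYSTEMS:
            sysmask = pa.mask(sys)
            rep1 = representativeness(m1, sysmask)
            rep2 = representativeness(m2, sysmask)
            eff1, _ = efficiency(m1, sysmask)
            eff2, _ = efficiency(m2, sysmask)
            eft = effectiveness(m1, m2, sysmask)
            records.append(
                IndexRecord(
                    species=s,
                    system=sys,
                    representativeness_t1=rep1,
                    representativeness_t2=rep2,
                    efficiency_t1=eff1,
                    efficiency_t2=eff2,
                    effectiveness=eft,
                    hsh_change_study_area=change_study,
                    hsh_change_in_system=hsh_change(m1, m2, sysmask),
                )
            )
            rep_mean = (
                0.5 * (rep1 + rep2)
                if _is_defined(rep1) and _is_defined(rep2)
                else Undefined("representativeness undefined at a date")
            )
            per_species[sys]["representativeness"][s] = rep_mean
            per_species[sys]["efficiency"][s] = 0.5 * (eff1 + eff2)
            per_species[sys]["effectiveness"][s] = eft

    weighted: dict[str, dict[str, float]] = {}
    for sys in SYSTEMS:
        weighted[sys] = {}
        for index_name, vals in per_species[sys].items():
            dropped = [s for s, v in vals.items() if not _is_defined(v)]
            for s in dropped:
                notes.append(f"{s} dropped from weighted {index_name} ({sys}): undefined")
            weighted[sys][index_name] = weighted_index(vals, statuses)

    return AssessmentReport(
        records=records,
        weighted=weighted,
        statuses=statuses,
        config_hash=config_digest(config or {}),
        seed=seed,
        notes=notes,
    )
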