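"""Two-level binarization of suitability maps: SH and HSH.

A continuous suitability map is reduced to two nested habitat layers:

* **SH** (suitable habitat): cells at or above the 10th percentile of the
  suitability values observed at the species' presence records — the
  standard percentile-training-presence rule, which bounds the omission
  error (at most ~10% of presences fall outside SH by construction);
* **HSH** (high-suitability habitat): SH cells at or above the mean
  suitability within SH — the species' priority areas.

"Above" is implemented as >= so constant maps do not yield empty masks;
HSH is nested in SH by construction. The percentile population defaults to
the presence records (config can switch to the whole-map distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .sdm import SuitabilityMap

__all__ = ["HabitatMask", "suitable_habitat", "high_suitability"]

logger = logging.getLogger(__name__)


@dataclass
class HabitatMask:
    """Boolean habitat raster plus the threshold that produced it."""

    data: np.ndarray
    level: str  # "SH" or "HSH"
    threshold: float
    source: SuitabilityMap
    species: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.level not in ("SH", "HSH"):
            raise ValueError("level must be 'SH' or 'HSH'")
        if self.data.shape != self.source.geometry.shape:
            raise ValueError("mask shape does not match source geometry")
        if self.species is None:
            self.species = self.source.species
        if self.year is None:
            self.year = self.source.year

    @property
    def geometry(self):
        return self.source.geometry

    def area_ha(self) -> float:
        return float(self.data.sum()) * self.geometry.cell_area_ha


def suitable_habitat(
    suitability: SuitabilityMap,
    presence_values: np.ndarray,
    percentile: float = 10.0,
) -> HabitatMask:
    """Suitable habitat: cells >= the ``percentile`` of presence suitability.

    The threshold is the linearly interpolated percentile of the
    suitability values at the presence records (10 values 0.1..1.0 give a
    10th percentile of 0.19).
    """
    values = np.asarray(presence_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty presence value set")
    if values.size < 10:
        logger.warning("suitable_habitat called with only %d presence values", values.size)
    threshold = float(np.percentile(values, percentile))
    mask = suitability.values >= threshold  # NaN compares False -> excluded
    return HabitatMask(mask, "SH", threshold, suitability)


def high_suitability(suitability: SuitabilityMap, sh: HabitatMask) -> HabitatMask:
    """High-suitability habitat: SH cells >= the mean suitability within SH."""
    if sh.source is not suitability and sh.source.geometry != suitability.geometry:
        raise ValueError("SH mask must derive from the same suitability map")
    sh_values = suitability.values[sh.data]
    if sh_values.size == 0:
        logger.warning("empty SH mask; HSH is empty too")
        return HabitatMask(np.zeros_like(sh.data), "HSH", np.nan, suitability)
    threshold = float(np.nanmean(sh_values))
    mask = sh.data & (suitability.values >= threshold)
    return HabitatMask(mask, "HSH", threshold, suitability)
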