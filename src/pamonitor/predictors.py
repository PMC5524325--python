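"""Multi-scale habitat-composition covariates from a categorical map.

Raptor habitat use operates at several nested spatial scales (nest site,
post-fledging family area, foraging range), so the suitability models are
fed the percentage of each land-cover class within circular windows of
500 m, 1 km, 2 km and 5 km radius. Two products are built here:

* a point table (one row per survey point, columns ``<Class>_<radius>``)
  used to calibrate the models, and
* per-class composition rasters at a coarser analysis grain (default
  500 m) used to project suitability wall-to-wall.

Cell membership in a window is decided by the cell-center-in-disc rule;
windows truncated at the map edge are renormalized over the cells actually
available, and a completeness flag records whether a window was whole.
Water and urban cover are computed internally but excluded from predictor
columns — the covariate schema carries the six vegetation/agriculture
classes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import NODATA_INT, GridGeometry
from .landcover import LULCMap

__all__ = [
    "CLASS_ACRONYMS",
    "PREDICTOR_CLASSES",
    "DEFAULT_RADII",
    "PredictorStack",
    "focal_composition",
    "extract_at_points",
]

#: Acronyms for the eight mapped classes, keyed by full palette label.
CLASS_ACRONYMS = {
    "deciduous forest": "DeFo",
    "coniferous forest": "CoFo",
    "closed shrubland": "CShr",
    "open shrubland": "OShr",
    "meadow/fallow": "Med",
    "arable": "ArL",
    "water": "Wat",
    "urban": "Urb",
}

#: Predictor column order (the deposited-table dialect; water/urban excluded).
PREDICTOR_CLASSES = ("OShr", "DeFo", "Med", "ArL", "CoFo", "CShr")

DEFAULT_RADII = (500.0, 1000.0, 2000.0, 5000.0)


@dataclass
class PredictorStack:
    """Per-class focal composition rasters at the analysis grain.

    ``layers`` maps a class acronym to a 2-D array of percentages in
    [0, 100] on ``geometry`` (the coarsened analysis grid); NaN marks
    windows with no valid source cell.
    """

    layers: dict[str, np.ndarray]
    radius: float
    grain: float
    geometry: GridGeometry

    def to_frame(self, classes: tuple[str, ...] = PREDICTOR_CLASSES) -> pd.DataFrame:
        """Flatten to one row per analysis cell, columns ``<acr>_<radius>``."""
        cols = {
            f"{acr}_{int(self.radius)}": self.layers[acr].ravel() for acr in classes
        }
        return pd.DataFrame(cols)

    def sample(self, x, y, acronym: str) -> np.ndarray:
        """Layer values at map coordinates (nearest analysis cell)."""
        row, col = self.geometry.index_of(x, y)
        row = np.clip(row, 0, self.geometry.rows - 1)
        col = np.clip(col, 0, self.geometry.cols - 1)
        return self.layers[acronym][row, col]


def _acronym_order(lulc: LULCMap) -> list[str]:
    return [CLASS_ACRONYMS.get(lab, lab) for lab in lulc.palette]


def _disc_offsets(radius: float, cell: float, frac_i: float, frac_j: float):
    """Source-index offsets whose cell centers fall within ``radius`` of a
    window center located at fractional position (frac_i, frac_j) inside
    source cell (0, 0)."""
    reach = int(np.ceil(radius / cell)) + 1
    di, dj = np.meshgrid(np.arange(-reach, reach + 1), np.arange(-reach, reach + 1), indexing="ij")
    dist2 = ((di - frac_i) ** 2 + (dj - frac_j) ** 2) * cell * cell
    keep = dist2 <= radius * radius + 1e-9
    return di[keep], dj[keep]


def focal_composition(lulc: LULCMap, radius: float, grain: float = 500.0) -> PredictorStack:
    """Percent cover of every class within ``radius`` of each analysis cell.

    The analysis grid has cell size ``grain`` (an integer multiple of the
    source cell size) and shares the source origin. For each analysis cell
    center, the percentage of non-nodata source cells whose centers lie in
    the disc is computed per class; windows containing no valid cell are
    NaN.
    """
    cell = lulc.geometry.cell_size
    if radius < cell:
        raise ValueError(f"radius {radius} is smaller than one source cell ({cell})")
    coarse = lulc.geometry.coarsen(grain)
    ratio = int(round(grain / cell))

    # Window centers sit at analysis-cell centers: source index
    # i = (I + 0.5) * ratio - 0.5, a constant fractional offset per grid.
    base_i = (np.arange(coarse.rows) + 0.5) * ratio - 0.5
    base_j = (np.arange(coarse.cols) + 0.5) * ratio - 0.5
    i0 = np.floor(base_i).astype(int)
    j0 = np.floor(base_j).astype(int)
    frac_i = float(base_i[0] - i0[0])
    frac_j = float(base_j[0] - j0[0])
    di, dj = _disc_offsets(radius, cell, frac_i, frac_j)

    acronyms = _acronym_order(lulc)
    k = len(acronyms)
    data = lulc.data
    counts = np.zeros((coarse.rows, coarse.cols, k))
    valid = np.zeros((coarse.rows, coarse.cols))
    rows, cols = lulc.geometry.shape
    for ci in range(coarse.rows):
        ii = i0[ci] + di
        ok_i = (ii >= 0) & (ii < rows)
        for cj in range(coarse.cols):
            jj = j0[cj] + dj
            ok = ok_i & (jj >= 0) & (jj < cols)
            vals = data[ii[ok], jj[ok]]
            vals = vals[vals != NODATA_INT]
            valid[ci, cj] = vals.size
            if vals.size:
                counts[ci, cj] = np.bincount(vals, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / valid[:, :, None]
    pct[valid == 0] = np.nan
    layers = {acr: pct[:, :, idx] for idx, acr in enumerate(acronyms)}
    return PredictorStack(layers=layers, radius=float(radius), grain=float(grain), geometry=coarse)


def extract_at_points(
    lulc: LULCMap,
    points: pd.DataFrame,
    radii=DEFAULT_RADII,
    classes: tuple[str, ...] = PREDICTOR_CLASSES,
) -> pd.DataFrame:
    """Focal composition around arbitrary map points (exact discs).

    ``points`` needs ``x``/``y`` columns; discs are centered on the points
    themselves, not snapped to the grid. Returns the input coordinates plus
    ``<acr>_<radius>`` percentage columns, a per-radius ``complete_<radius>``
    flag (False when the window was truncated by the map edge), and an
    ``in_bounds`` flag; out-of-bounds points are flagged, not dropped.
    """
    geom = lulc.geometry
    acronyms = _acronym_order(lulc)
    k = len(acronyms)
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    in_bounds = geom.contains(x, y)
    out = {"x": x, "y": y}
    cell = geom.cell_size
    xc = geom.x_centers()
    yc = geom.y_centers()
    for radius in radii:
        if radius < cell:
            raise ValueError(f"radius {radius} is smaller than one source cell")
        reach = int(np.ceil(radius / cell)) + 1
        pct = np.full((len(x), k), np.nan)
        xmin, ymin, xmax, ymax = geom.bounds
        # a window is complete iff the disc clears every map edge and
        # contains no nodata cells
        clears_edge = (
            (x - xmin >= radius)
            & (xmax - x >= radius)
            & (y - ymin >= radius)
            & (ymax - y >= radius)
        )
        complete = np.zeros(len(x), dtype=bool)
        for p in range(len(x)):
            if not in_bounds[p]:
                continue
            row, col = geom.index_of(x[p], y[p])
            ri = slice(max(row - reach, 0), min(row + reach + 1, geom.rows))
            rj = slice(max(col - reach, 0), min(col + reach + 1, geom.cols))
            dx = xc[rj] - x[p]
            dy = yc[ri] - y[p]
            mask = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius * radius + 1e-9
            vals = lulc.data[ri, rj][mask]
            n_in_disc = vals.size
            vals = vals[vals != NODATA_INT]
            complete[p] = bool(clears_edge[p]) and n_in_disc == vals.size
            if vals.size:
                pct[p] = 100.0 * np.bincount(vals, minlength=k) / vals.size
        for idx, acr in enumerate(acronyms):
            if acr in classes:
                out[f"{acr}_{int(radius)}"] = pct[:, idx]
        out[f"complete_{int(radius)}"] = complete
    out["in_bounds"] = in_bounds
    table = pd.DataFrame(out)
    ordered = ["x", "y"] + [
        f"{acr}_{int(r)}" for r in radii for acr in classes
    ] + [f"complete_{int(r)}" for r in radii] + ["in_bounds"]
    return table[ordered]
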