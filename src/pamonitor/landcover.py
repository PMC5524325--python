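"""Supervised per-pixel classification of multispectral scenes.

Implements the remote-sensing leg of the monitoring protocol: NDVI as an
optional ancillary band, Gaussian class signatures estimated from training
cells, three classical per-pixel classifiers (maximum likelihood,
Mahalanobis distance, spectral angle mapper), transformed-divergence
separability screening of the training statistics, and confusion-matrix
accuracy assessment of the resulting categorical maps.

The maximum-likelihood rule assigns each pixel x the class maximizing

    ln p_k - 1/2 ln|Sigma_k| - 1/2 (x - mu_k)^T Sigma_k^-1 (x - mu_k),

the Mahalanobis rule minimizes the quadratic form alone (a pooled-geometry
shortcut that coincides with maximum likelihood when covariances and priors
are shared), and the spectral angle mapper minimizes the angle between the
pixel vector and the class mean, which makes it insensitive to overall
brightness. Ties are broken toward the lowest class id so outputs are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .grid import NODATA_INT, GridGeometry

__all__ = [
    "SpectralScene",
    "LULCMap",
    "ClassSignature",
    "ConfusionMatrix",
    "SingularSignatureError",
    "compute_ndvi",
    "fit_signatures",
    "classify_scene",
    "transformed_divergence",
    "screen_separability",
    "assess_accuracy",
]

logger = logging.getLogger(__name__)

CLASSIFIER_METHODS = ("max_likelihood", "mahalanobis", "spectral_angle")


class SingularSignatureError(ValueError):
    """A class signature's covariance matrix is singular."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"singular covariance for class {label!r}")


@dataclass
class SpectralScene:
    """Multiband reflectance raster on a shared grid.

    ``bands`` has shape (B, rows, cols); nodata cells are NaN in every band.
    """

    bands: np.ndarray
    geometry: GridGeometry
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[0] < 2:
            raise ValueError("scene needs a (B, rows, cols) array with B >= 2")
        if self.bands.shape[1:] != self.geometry.shape:
            raise ValueError("band shape does not match geometry")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.bands).any(axis=0)

    def with_band(self, band: np.ndarray, name: str = "ancillary") -> "SpectralScene":
        """A new scene with one extra band appended (e.g. NDVI)."""
        names = self.band_names or tuple(f"b{i+1}" for i in range(self.n_bands))
        return SpectralScene(
            bands=np.concatenate([self.bands, band[None]], axis=0),
            geometry=self.geometry,
            band_names=names + (name,),
        )


@dataclass
class LULCMap:
    """Categorical land-use/land-cover raster; -1 encodes nodata."""

    data: np.ndarray
    palette: tuple[str, ...]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.shape != self.geometry.shape:
            raise ValueError("data shape does not match geometry")
        valid = self.data[self.data != NODATA_INT]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.palette)):
            raise ValueError("class ids outside palette range")

    def class_fractions(self) -> np.ndarray:
        """Share of valid cells per palette class."""
        valid = self.data[self.data != NODATA_INT]
        counts = np.bincount(valid, minlength=len(self.palette))
        return counts / max(valid.size, 1)


@dataclass
class ClassSignature:
    """Gaussian spectral signature of one LULC class."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    prior: float = 0.0
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        b = self.mean.size
        if self.cov.shape != (b, b):
            raise ValueError(f"covariance shape {self.cov.shape} != ({b}, {b})")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError(f"covariance for {self.label!r} is not symmetric")


@dataclass
class ConfusionMatrix:
    """K x K count table: reference classes in rows, predictions in columns."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    @property
    def kappa(self) -> float:
        """Cohen's kappa: (po - pe) / (1 - pe) with pe from the marginals."""
        n = self.total
        po = np.trace(self.counts) / n
        pe = float(self.counts.sum(axis=1) @ self.counts.sum(axis=0)) / (n * n)
        if pe == 1.0:
            return 1.0
        return float((po - pe) / (1.0 - pe))


def compute_ndvi(scene: SpectralScene, red_band: int, nir_band: int) -> np.ndarray:
    """Normalized difference vegetation index (NIR - Red) / (NIR + Red).

    Cells where NIR + Red == 0 are returned as NaN (nodata).
    """
    if red_band == nir_band:
        raise ValueError("red and NIR band indices must differ")
    red = scene.bands[red_band]
    nir = scene.bands[nir_band]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    return ndvi


def fit_signatures(
    scene: SpectralScene,
    training: dict[str, np.ndarray],
    priors: dict[str, float] | None = None,
) -> list[ClassSignature]:
    """Estimate per-class Gaussian signatures from labeled training cells.

    ``training`` maps each class label to an (n, 2) array of (row, col)
    cell indices; n must exceed the band count so the sample covariance is
    invertible. Priors default to equal (training areas are digitized
    polygons, not an area-proportional sample of the scene).
    """
    labels = list(training)
    if priors is None:
        priors = {lab: 1.0 / len(labels) for lab in labels}
    else:
        missing = set(labels) - set(priors)
        if missing:
            raise ValueError(f"priors missing for classes: {sorted(missing)}")
        total = sum(priors[lab] for lab in labels)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
    b = scene.n_bands
    signatures = []
    for lab in labels:
        cells = np.asarray(training[lab])
        if cells.ndim != 2 or cells.shape[1] != 2:
            raise ValueError(f"training cells for {lab!r} must be (n, 2) row/col")
        if cells.shape[0] < b + 1:
            raise ValueError(
                f"class {lab!r} has {cells.shape[0]} training cells; "
                f"need at least {b + 1} for an invertible covariance"
            )
        samples = scene.bands[:, cells[:, 0], cells[:, 1]].T  # (n, B)
        if np.isnan(samples).any():
            raise ValueError(f"training cells for {lab!r} include nodata pixels")
        mean = samples.mean(axis=0)
        cov = np.cov(samples, rowvar=False)
        sig = ClassSignature(lab, mean, cov, prior=priors[lab], n_samples=len(samples))
        if np.linalg.matrix_rank(cov) < b or np.linalg.cond(cov) > 1e12:
            raise SingularSignatureError(lab)
        signatures.append(sig)
    return signatures


def _mahalanobis_sq(pixels: np.ndarray, sig: ClassSignature) -> np.ndarray:
    """Squared Mahalanobis distance of (n, B) pixels to a signature."""
    diff = pixels - sig.mean
    try:
        solve = np.linalg.solve(sig.cov, diff.T)
    except np.linalg.LinAlgError as exc:
        raise SingularSignatureError(sig.label) from exc
    return np.einsum("ij,ji->i", diff, solve)


def classify_scene(
    scene: SpectralScene,
    signatures: list[ClassSignature],
    method: str = "max_likelihood",
) -> LULCMap:
    """Classify every pixel of a scene into one of the signature classes.

    Nodata pixels propagate; under ``spectral_angle`` zero-norm pixels
    become nodata too (the angle is undefined) with a logged count.
    """
    if method not in CLASSIFIER_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {CLASSIFIER_METHODS}")
    palette = tuple(sig.label for sig in signatures)
    rows, cols = scene.geometry.shape
    flat = scene.bands.reshape(scene.n_bands, -1).T  # (n, B)
    invalid = np.isnan(flat).any(axis=1)
    pixels = np.where(invalid[:, None], 0.0, flat)

    k = len(signatures)
    scores = np.empty((k, pixels.shape[0]))
    if method == "spectral_angle":
        norms = np.linalg.norm(pixels, axis=1)
        zero_norm = (norms == 0) & ~invalid
        if zero_norm.any():
            logger.warning(
                "spectral_angle: %d zero-norm pixels set to nodata", int(zero_norm.sum())
            )
        for i, sig in enumerate(signatures):
            mu_norm = np.linalg.norm(sig.mean)
            if mu_norm == 0:
                raise ValueError(f"class {sig.label!r} has a zero mean vector")
            cosine = pixels @ sig.mean / np.where(norms == 0, 1.0, norms * mu_norm)
            scores[i] = -np.arccos(np.clip(cosine, -1.0, 1.0))
        invalid = invalid | zero_norm
    else:
        for i, sig in enumerate(signatures):
            d2 = _mahalanobis_sq(pixels, sig)
            if method == "max_likelihood":
                sign, logdet = np.linalg.slogdet(sig.cov)
                if sign <= 0:
                    raise SingularSignatureError(sig.label)
                prior = sig.prior if sig.prior > 0 else 1.0 / k
                scores[i] = np.log(prior) - 0.5 * logdet - 0.5 * d2
            else:
                scores[i] = -d2

    labels = np.argmax(scores, axis=0).astype(np.int16)  # first max = lowest id
    labels[invalid] = NODATA_INT
    return LULCMap(labels.reshape(rows, cols), palette, scene.geometry)


def transformed_divergence(a: ClassSignature, b: ClassSignature) -> float:
    """Transformed divergence separability of two Gaussian signatures.

    D  = 1/2 tr[(Sa - Sb)(Sb^-1 - Sa^-1)]
       + 1/2 tr[(Sa^-1 + Sb^-1)(mu_a - mu_b)(mu_a - mu_b)^T]
    TD = 2 (1 - exp(-D / 8))

    TD is symmetric and bounded in [0, 2]; values above ~1.99 indicate
    near-perfect statistical separability of the two classes.
    """
    try:
        inv_a = np.linalg.inv(a.cov)
        inv_b = np.linalg.inv(b.cov)
    except np.linalg.LinAlgError as exc:
        raise SingularSignatureError(f"{a.label}/{b.label}") from exc
    dm = (a.mean - b.mean)[:, None]
    d = 0.5 * np.trace((a.cov - b.cov) @ (inv_b - inv_a)) + 0.5 * np.trace(
        (inv_a + inv_b) @ (dm @ dm.T)
    )
    return float(2.0 * (1.0 - np.exp(-d / 8.0)))


def screen_separability(
    signatures: list[ClassSignature], threshold: float = 1.99
) -> list[tuple[str, str, float]]:
    """All unordered signature pairs with TD <= threshold (worst first).

    An empty report means every class pair in the training set is
    separable above the threshold.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures to screen")
    flagged = []
    for i in range(len(signatures)):
        for j in range(i + 1, len(signatures)):
            td = transformed_divergence(signatures[i], signatures[j])
            if td <= threshold:
                flagged.append((signatures[i].label, signatures[j].label, td))
    flagged.sort(key=lambda t: t[2])
    return flagged


def assess_accuracy(
    predicted: LULCMap,
    reference_cells: np.ndarray,
    reference_labels: np.ndarray,
) -> ConfusionMatrix:
    """Cross-tabulate predicted classes against labeled reference cells.

    ``reference_cells`` is (n, 2) row/col indices on the map grid;
    ``reference_labels`` the matching class ids. Cells where the
    prediction is nodata are dropped.
    """
    cells = np.asarray(reference_cells)
    ref = np.asarray(reference_labels)
    if cells.size == 0:
        raise ValueError("empty reference set")
    if cells.ndim != 2 or cells.shape[1] != 2 or len(ref) != len(cells):
        raise ValueError("reference cells must be (n, 2) with n matching labels")
    rows, cols = predicted.geometry.shape
    if (cells[:, 0] < 0).any() or (cells[:, 0] >= rows).any() or (
        cells[:, 1] < 0
    ).any() or (cells[:, 1] >= cols).any():
        raise ValueError("reference cells outside the map grid")
    pred = predicted.data[cells[:, 0], cells[:, 1]]
    keep = pred != NODATA_INT
    if not keep.any():
        raise ValueError("all reference cells fall on nodata predictions")
    ids = np.arange(len(predicted.palette))
    counts = _sk_confusion(ref[keep], pred[keep], labels=ids)
    return ConfusionMatrix(counts, predicted.palette)
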