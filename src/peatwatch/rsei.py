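"""Per-year PCA synthesis of NDVI, WET, NDBSI and LST into a [0,1] condition
index, its five-level categorisation and class-stratified summaries.

The four indicator layers are min-max normalized over the year's valid ROI
pixels, centred, and reduced with covariance PCA.  The leading component is
oriented so the index correlates positively with greenness/wetness and
negatively with dryness/heat (the eigenvector sign is arbitrary, so "invert
PC1" is implemented as this correlation rule), then min-max rescaled to
[0,1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, require_same_grid
from .landcover import CLASS_CODES, CLASS_NAMES, LandCoverMap

log = logging.getLogger(__name__)

COMPONENT_ORDER = ("NDVI", "WET", "NDBSI", "LST")
#: sign each component must carry in the oriented index
COMPONENT_SIGNS = {"NDVI": +1, "WET": +1, "NDBSI": -1, "LST": -1}

CATEGORY_NAMES = {1: "Poor", 2: "Satisfactory", 3: "Moderate", 4: "Good", 5: "Excellent"}


class ConstantLayerError(ValueError):
    pass


@dataclass
class RSEIResult:
    year: int
    normalized_components: dict      # name -> [0,1] raster
    pc1_loadings: np.ndarray         # 4 reals, unit norm, order COMPONENT_ORDER
    pc1_variance_share: float
    rsei: np.ndarray                 # [0,1] raster, NaN invalid
    categories: np.ndarray           # {1..5}, 0 nodata
    orientation_flipped: bool
    grid: RasterGrid | None = None

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.rsei)


def normalize01(layer: np.ndarray, name: str = "layer") -> np.ndarray:
    """(x - min) / (max - min) over valid pixels; constant layers are an error."""
    x = np.asarray(layer, dtype=np.float64)
    valid = np.isfinite(x)
    if valid.sum() < 2:
        raise ConstantLayerError(f"component {name!r} has fewer than 2 valid pixels")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ConstantLayerError(f"component {name!r} is constant; cannot normalize")
    return (x - lo) / (hi - lo)


def pca_pc1(layers: dict):
    """Leading principal component of the four centred component layers.

    Returns (loadings, scores, variance_share).  Scores are NaN outside the
    common valid mask.  A rank-deficient covariance is flagged (warning) but
    the leading eigenvector is still returned.
    """
    names = list(COMPONENT_ORDER)
    stack = np.stack([np.asarray(layers[n], dtype=np.float64) for n in names])
    valid = np.isfinite(stack).all(axis=0)
    if valid.sum() < 4:
        raise ValueError("need at least 4 pixels valid in all four components")
    X = stack[:, valid].T                               # (n, 4)
    X = X - X.mean(axis=0)
    cov = (X.T @ X) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)              # ascending
    if np.linalg.matrix_rank(cov) < 4:
        log.warning("rank-deficient component covariance (rank %d)",
                    np.linalg.matrix_rank(cov))
    pc1 = eigvecs[:, -1]
    variance_share = float(eigvals[-1] / eigvals.sum()) if eigvals.sum() > 0 else 1.0
    scores = np.full(stack.shape[1:], np.nan)
    scores[valid] = X @ pc1
    return pc1, scores, variance_share


def compute_rsei(scores: np.ndarray, loadings: np.ndarray, layers: dict):
    """Orient PC1 (positive greenness loading) and min-max rescale to [0,1].

    Returns (rsei, orientation_flipped).  Flipping the score sign is the
    normalized equivalent of taking 1 - PC1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    ndvi_loading = loadings[COMPONENT_ORDER.index("NDVI")]
    flipped = ndvi_loading < 0
    raw = -scores if flipped else scores
    valid = np.isfinite(raw)
    if not valid.any() or np.nanmax(raw) == np.nanmin(raw):
        raise ValueError("index scores have zero variance")
    return normalize01(raw, "RSEI"), bool(flipped)


def classify_rsei(rsei: np.ndarray) -> np.ndarray:
    """Five 0.2-wide categories, left-closed bins, last bin closed at 1.

    Codes 1..5; out-of-range or invalid input becomes 0 (nodata).
    """
    x = np.asarray(rsei, dtype=np.float64)
    cats = np.zeros(x.shape, dtype=np.int16)
    ok = np.isfinite(x) & (x >= 0.0) & (x <= 1.0)
    binned = np.minimum(np.floor(x[ok] / 0.2), 4).astype(np.int16) + 1
    cats[ok] = binned
    return cats


def rsei_for_year(year: int, components: dict, grid: RasterGrid | None = None) -> RSEIResult:
    """Full per-year pipeline: normalize -> PCA -> orient/rescale -> categorise."""
    normalized = {n: normalize01(components[n], n) for n in COMPONENT_ORDER}
    loadings, scores, variance_share = pca_pc1(normalized)
    rsei, flipped = compute_rsei(scores, loadings, normalized)
    oriented = -loadings if flipped else loadings
    return RSEIResult(
        year=year,
        normalized_components=normalized,
        pc1_loadings=oriented,
        pc1_variance_share=variance_share,
        rsei=rsei,
        categories=classify_rsei(rsei),
        orientation_flipped=flipped,
        grid=grid,
    )


def stratified_mean(rsei: np.ndarray, landcover_map: LandCoverMap) -> dict:
    """Mean index over the valid pixels of each class, with pixel counts.

    Empty classes yield (nan, 0) and are flagged with a warning.
    """
    x = np.asarray(rsei, dtype=np.float64)
    if x.shape != landcover_map.grid.shape:
        raise ValueError("grid mismatch between index layer and land-cover map")
    out = {}
    for code in CLASS_CODES:
        mask = landcover_map.mask(code) & np.isfinite(x)
        n = int(mask.sum())
        if n == 0:
            log.warning("stratified_mean: class %s is empty", CLASS_NAMES[code])
            out[code] = (float("nan"), 0)
        else:
            out[code] = (float(x[mask].mean()), n)
    return out


def category_areas(categories: np.ndarray, pixel_area_ha: float) -> dict:
    """Hectares per condition category (codes 1..5)."""
    return {c: float((categories == c).sum() * pixel_area_ha) for c in CATEGORY_NAMES}
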