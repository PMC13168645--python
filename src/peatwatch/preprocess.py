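"""QA decoding, product scaling, seasonal scene selection and medoid compositing.

Turns a stack of per-year acquisitions into one analysis-ready composite per
year.  The composite is a *medoid*: for every pixel the single observed
spectrum closest (Euclidean distance over the six reflectance bands) to the
per-band median is copied into all bands, so composite spectra are always
spectra that were actually observed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid, require_same_grid

#: canonical reflectance band order used throughout the package
BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
N_BANDS = len(BANDS)

#: Collection-2 Level-2 product scaling (reflectance and surface temperature)
REFLECTANCE_SCALE = 2.75e-5
REFLECTANCE_OFFSET = -0.2
TEMPERATURE_SCALE = 0.00341802
TEMPERATURE_OFFSET = 149.0


class Sensor(str, enum.Enum):
    TM = "TM"
    ETM = "ETM+"
    OLI = "OLI"
    SYNTHETIC = "SYNTHETIC"


class Window(str, enum.Enum):
    JUNE = "JUNE"
    JJA = "JJA"
    EXTENDED = "EXTENDED"


# day-of-year windows (non-leap convention; a +/-1 day slack is irrelevant here)
JUNE_DOY = (152, 181)
JJA_DOY = (152, 243)


@dataclass
class QABitSpec:
    """Bit positions of the pixel-quality flags to be treated as invalid."""

    fill: int = 0
    cirrus: int = 2
    cloud: int = 3
    cloud_shadow: int = 4
    snow_ice: int = 5
    #: bits of the parallel radiometric-saturation word (any set bit drops the pixel)
    saturation_bits: tuple = (0, 1, 2, 3, 4, 5)

    def __post_init__(self):
        positions = [self.fill, self.cirrus, self.cloud, self.cloud_shadow, self.snow_ice]
        if len(set(positions)) != len(positions):
            raise ValueError("QA bit positions must be distinct")
        if any(p < 0 or p >= 32 for p in positions):
            raise ValueError("QA bit positions must fit a 32-bit word")

    @property
    def invalid_mask_word(self) -> int:
        word = 0
        for p in (self.fill, self.cirrus, self.cloud, self.cloud_shadow, self.snow_ice):
            word |= 1 << p
        return word


@dataclass
class SceneStack:
    """One acquisition: six reflectance bands, a thermal band and a QA word."""

    year: int
    acquisition_doy: int
    sensor_id: Sensor
    bands: np.ndarray        # (6, rows, cols) float, unitless reflectance
    thermal: np.ndarray      # (rows, cols) float (Kelvin for SYNTHETIC / scaled products)
    qa: np.ndarray           # (rows, cols) integer bit flags
    grid: RasterGrid
    saturation: np.ndarray | None = None  # optional parallel saturation word

    def __post_init__(self):
        if self.bands.shape != (N_BANDS, *self.grid.shape):
            raise ValueError("band stack does not match grid")
        if self.thermal.shape != self.grid.shape or self.qa.shape != self.grid.shape:
            raise ValueError("thermal/qa raster does not match grid")

    def band(self, name: str) -> np.ndarray:
        return self.bands[BANDS.index(name)]


@dataclass
class Composite:
    """Annual medoid composite plus per-pixel contributing-observation count."""

    year: int
    bands: np.ndarray        # (6, rows, cols); NaN where no valid observation
    thermal: np.ndarray
    grid: RasterGrid
    valid_count: np.ndarray  # (rows, cols) int
    window_used: Window = Window.JJA
    source_doy: np.ndarray | None = None  # DOY of the chosen observation

    def band(self, name: str) -> np.ndarray:
        return self.bands[BANDS.index(name)]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.valid_count > 0


def decode_qa(qa_raster: np.ndarray, spec: QABitSpec,
              saturation_raster: np.ndarray | None = None) -> np.ndarray:
    """Boolean validity mask: True where no flagged bit is set.

    A pixel is valid iff none of fill/cirrus/cloud/cloud-shadow/snow-ice bits
    are set in the QA word and (if given) no saturation bit is set in the
    parallel saturation word.  Saturation drops the whole pixel vector so that
    composite spectra stay internally consistent.
    """
    qa = np.asarray(qa_raster).astype(np.int64)
    valid = (qa & spec.invalid_mask_word) == 0
    if saturation_raster is not None:
        sat_word = 0
        for p in spec.saturation_bits:
            sat_word |= 1 << p
        valid &= (np.asarray(saturation_raster).astype(np.int64) & sat_word) == 0
    return valid


def scale_reflectance(dn_raster: np.ndarray) -> np.ndarray:
    """Scale Level-2 reflectance DN to unitless reflectance.

    Values outside [0, 1] are marked invalid (NaN), never clipped.
    """
    refl = np.asarray(dn_raster, dtype=np.float64) * REFLECTANCE_SCALE + REFLECTANCE_OFFSET
    out = np.where((refl < 0.0) | (refl > 1.0), np.nan, refl)
    return out


def scale_temperature(dn_raster: np.ndarray) -> np.ndarray:
    """Scale Level-2 surface-temperature DN to degrees Celsius."""
    kelvin = np.asarray(dn_raster, dtype=np.float64) * TEMPERATURE_SCALE + TEMPERATURE_OFFSET
    return kelvin - 273.15


@dataclass
class SeasonalSelection:
    scenes: list
    window_used: Window | None
    missing: bool = False
    june_coverage: float = 0.0


def _coverage(scenes, spec: QABitSpec) -> float:
    """Fraction of pixels with >=1 valid observation across the given scenes."""
    if not scenes:
        return 0.0
    any_valid = np.zeros(scenes[0].grid.shape, dtype=bool)
    for sc in scenes:
        any_valid |= decode_qa(sc.qa, spec, sc.saturation)
    return float(any_valid.mean())


def select_seasonal_scenes(scenes, year: int, spec: QABitSpec | None = None,
                           coverage_threshold: float = 0.8) -> SeasonalSelection:
    """Pick the June subset if its clear-sky coverage is adequate, else JJA.

    Coverage is adequate when the fraction of pixels with at least one valid
    observation reaches ``coverage_threshold``.  A year whose extended-window
    scenes give zero coverage is flagged missing rather than fabricated.
    """
    spec = spec or QABitSpec()
    year_scenes = [s for s in scenes if s.year == year]
    june = [s for s in year_scenes if JUNE_DOY[0] <= s.acquisition_doy <= JUNE_DOY[1]]
    jja = [s for s in year_scenes if JJA_DOY[0] <= s.acquisition_doy <= JJA_DOY[1]]

    june_cov = _coverage(june, spec)
    if june and june_cov >= coverage_threshold:
        return SeasonalSelection(june, Window.JUNE, june_coverage=june_cov)
    if not jja or _coverage(jja, spec) == 0.0:
        return SeasonalSelection([], None, missing=True, june_coverage=june_cov)
    return SeasonalSelection(jja, Window.JJA, june_coverage=june_cov)


def medoid_composite(scenes, spec: QABitSpec | None = None,
                     window_used: Window = Window.JJA) -> Composite:
    """Per-pixel medoid composite over the given scenes.

    For every pixel the per-band median over valid observations is computed,
    then the single valid observation minimising the Euclidean distance (over
    the six reflectance bands) to that median vector is copied into all bands
    including thermal.  Ties are broken by earliest acquisition date.
    """
    if not scenes:
        raise ValueError("medoid_composite needs at least one scene")
    spec = spec or QABitSpec()
    grid = require_same_grid(*[s.grid for s in scenes])
    # stable order: earliest DOY first, so argmin tie-break = earliest date
    scenes = sorted(scenes, key=lambda s: s.acquisition_doy)

    cube = np.stack([s.bands for s in scenes])                 # (n, 6, r, c)
    thermal = np.stack([s.thermal for s in scenes])            # (n, r, c)
    valid = np.stack([decode_qa(s.qa, spec, s.saturation) for s in scenes])
    valid &= np.isfinite(cube).all(axis=1)

    cube_masked = np.where(valid[:, None], cube, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        median = np.nanmedian(cube_masked, axis=0)             # (6, r, c)
        dist2 = np.nansum((cube_masked - median[None]) ** 2, axis=1)
    dist2 = np.where(valid, dist2, np.inf)

    choice = np.argmin(dist2, axis=0)                          # (r, c)
    valid_count = valid.sum(axis=0).astype(np.int32)
    any_valid = valid_count > 0

    rows, cols = grid.shape
    rr, cc = np.indices((rows, cols))
    out_bands = cube[choice, :, rr, cc].transpose(2, 0, 1).astype(np.float64)
    out_thermal = thermal[choice, rr, cc].astype(np.float64)
    out_bands[:, ~any_valid] = np.nan
    out_thermal[~any_valid] = np.nan

    doys = np.array([s.acquisition_doy for s in scenes])
    source_doy = np.where(any_valid, doys[choice], -1).astype(np.int32)

    return Composite(
        year=scenes[0].year,
        bands=out_bands,
        thermal=out_thermal,
        grid=grid,
        valid_count=valid_count,
        window_used=window_used,
        source_doy=source_doy,
    )


def composite_year(scenes, year: int, spec: QABitSpec | None = None,
                   coverage_threshold: float = 0.8) -> Composite | None:
    """Seasonal selection + medoid compositing for one year (None if missing)."""
    sel = select_seasonal_scenes(scenes, year, spec, coverage_threshold)
    if sel.missing:
        return None
    return medoid_composite(sel.scenes, spec, window_used=sel.window_used)
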