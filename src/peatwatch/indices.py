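"""Spectral indicators: classification predictors and condition-index components.

Normalized-difference indices (NDVI, NDMI, NBR, MNDWI), Tasseled-Cap wetness,
the bare-surface composite NDBSI = (SI + IBI)/2, and land-surface temperature
via either the scaled surface-temperature product (default) or a
single-channel emissivity-corrected brightness-temperature formula.

Two SI variants are shipped.  ``table_verbatim`` implements the formula
exactly as printed in the source table, which algebraically reduces to a
red-blue contrast ``(B_red - B_blue) / (2*B_nir + B_red + B_blue)`` with no
SWIR term.  ``standard_si`` is the conventional bare-soil index
``[(B_swir1 + B_red) - (B_nir + B_blue)] / [(B_swir1 + B_red) + (B_nir + B_blue)]``.
Neither is presented as more authoritative; the verbatim form is the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import BANDS, Composite, Sensor

#: h*c/sigma in m*K, used by the single-channel LST formula
RHO_M_K = 1.438e-2


class IndexName(str, enum.Enum):
    NDVI = "NDVI"
    NDMI = "NDMI"
    NBR = "NBR"
    MNDWI = "MNDWI"
    WET = "WET"
    SI = "SI"
    IBI = "IBI"
    NDBSI = "NDBSI"
    BT = "BT"
    LST = "LST"


class SIVariant(str, enum.Enum):
    TABLE_VERBATIM = "table_verbatim"
    STANDARD_SI = "standard_si"


@dataclass
class SensorCoefficients:
    """Per-sensor wetness betas and thermal calibration constants."""

    sensor_id: Sensor
    wet_betas: np.ndarray       # 6 reals, band order blue..swir2
    K1: float
    K2: float
    lambda_m: float             # effective thermal wavelength (m)
    rho: float = RHO_M_K

    def __post_init__(self):
        self.wet_betas = np.asarray(self.wet_betas, dtype=np.float64)
        if self.wet_betas.shape != (6,):
            raise ValueError("wet_betas must have 6 entries")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be positive")


@dataclass
class IndexLayer:
    name: IndexName
    values: np.ndarray   # NaN = invalid

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def _load_coefficient_table() -> pd.DataFrame:
    path = resources.files("peatwatch").joinpath("data/wetness_coefficients.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


_COEFF_TABLE = None


def sensor_coefficients(sensor_id: Sensor | str) -> SensorCoefficients:
    """Look up the registered coefficient set for a sensor."""
    global _COEFF_TABLE
    if _COEFF_TABLE is None:
        _COEFF_TABLE = _load_coefficient_table()
    sid = Sensor(sensor_id)
    row = _COEFF_TABLE[_COEFF_TABLE.sensor_id == sid.value]
    if row.empty:
        raise KeyError(f"no coefficient set registered for sensor {sid.value}")
    row = row.iloc[0]
    return SensorCoefficients(
        sensor_id=sid,
        wet_betas=row[list(BANDS)].to_numpy(dtype=np.float64),
        K1=float(row.K1),
        K2=float(row.K2),
        lambda_m=float(row.lambda_m),
    )


def normalized_difference(band_a: np.ndarray, band_b: np.ndarray,
                          name: IndexName = IndexName.NDVI) -> IndexLayer:
    """(a - b) / (a + b); zero denominators become nodata, not exceptions."""
    a = np.asarray(band_a, dtype=np.float64)
    b = np.asarray(band_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("band grids differ")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0.0, np.nan, (a - b) / denom)
    return IndexLayer(name, out)


def ndvi(composite: Composite) -> IndexLayer:
    return normalized_difference(composite.band("nir"), composite.band("red"), IndexName.NDVI)


def ndmi(composite: Composite) -> IndexLayer:
    return normalized_difference(composite.band("nir"), composite.band("swir1"), IndexName.NDMI)


def nbr(composite: Composite) -> IndexLayer:
    return normalized_difference(composite.band("nir"), composite.band("swir2"), IndexName.NBR)


def mndwi(composite: Composite) -> IndexLayer:
    return normalized_difference(composite.band("green"), composite.band("swir1"), IndexName.MNDWI)


def tasseled_cap_wetness(composite: Composite,
                         coefficients: SensorCoefficients | None = None,
                         sensor_id: Sensor | str | None = None) -> IndexLayer:
    """Per-pixel dot product of the six reflectance bands with the wetness betas."""
    if coefficients is None:
        if sensor_id is None:
            raise ValueError("pass coefficients or a sensor_id with a registered set")
        coefficients = sensor_coefficients(sensor_id)
    wet = np.tensordot(coefficients.wet_betas, composite.bands, axes=(0, 0))
    return IndexLayer(IndexName.WET, wet)


def soil_index(composite: Composite,
               variant: SIVariant = SIVariant.TABLE_VERBATIM) -> IndexLayer:
    blue = composite.band("blue")
    red = composite.band("red")
    nir_ = composite.band("nir")
    swir1 = composite.band("swir1")
    if variant == SIVariant.TABLE_VERBATIM:
        num = (nir_ + red) - (nir_ + blue)          # = red - blue, as printed
        den = (nir_ + red) + (nir_ + blue)
    else:
        num = (swir1 + red) - (nir_ + blue)
        den = (swir1 + red) + (nir_ + blue)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den == 0.0, np.nan, num / den)
    return IndexLayer(IndexName.SI, out)


def building_index(composite: Composite) -> IndexLayer:
    green = composite.band("green")
    red = composite.band("red")
    nir_ = composite.band("nir")
    swir1 = composite.band("swir1")
    swir2 = composite.band("swir2")
    with np.errstate(invalid="ignore", divide="ignore"):
        built = 2.0 * swir2 / (swir1 + nir_)
        veg = nir_ / (red + nir_) + green / (swir1 + green)
        den = built + veg
        out = np.where(np.isfinite(den) & (den != 0.0), (built - veg) / den, np.nan)
    return IndexLayer(IndexName.IBI, out)


def ndbsi(composite: Composite,
          variant: SIVariant = SIVariant.TABLE_VERBATIM) -> IndexLayer:
    """Mean of the soil and building indices: (SI + IBI) / 2."""
    si = soil_index(composite, variant)
    ibi = building_index(composite)
    return IndexLayer(IndexName.NDBSI, (si.values + ibi.values) / 2.0)


def brightness_temperature(thermal_radiance: np.ndarray,
                           coefficients: SensorCoefficients,
                           radiance_cap: float = 1.0e4) -> IndexLayer:
    """T = K2 / ln(K1/L + 1), Kelvin; L <= 0 or above the cap -> nodata.

    Without a cap, T diverges as L grows (ln -> 0), so radiances above
    ``radiance_cap`` are flagged invalid rather than returned as huge values.
    """
    L = np.asarray(thermal_radiance, dtype=np.float64)
    ok = np.isfinite(L) & (L > 0.0) & (L <= radiance_cap)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coefficients.K2 / np.log(coefficients.K1 / L + 1.0)
    return IndexLayer(IndexName.BT, np.where(ok, t, np.nan))


def lst_single_channel(t_kelvin: np.ndarray, emissivity: np.ndarray | float,
                       coefficients: SensorCoefficients) -> IndexLayer:
    """LST (deg C) = T / [1 + (lambda*T/rho) ln eps] - 273.15."""
    T = np.asarray(t_kelvin, dtype=np.float64)
    eps = np.broadcast_to(np.asarray(emissivity, dtype=np.float64), T.shape)
    ok = np.isfinite(T) & (T > 0.0) & (eps > 0.0) & (eps <= 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lst = T / (1.0 + (coefficients.lambda_m * T / coefficients.rho) * np.log(eps)) - 273.15
    return IndexLayer(IndexName.LST, np.where(ok, lst, np.nan))


def lst_from_product(scaled_temperature_c: np.ndarray,
                     bounds: tuple = (-20.0, 60.0)) -> IndexLayer:
    """Product-derived LST passthrough with plausibility screening (deg C)."""
    t = np.asarray(scaled_temperature_c, dtype=np.float64)
    ok = np.isfinite(t) & (t >= bounds[0]) & (t <= bounds[1])
    return IndexLayer(IndexName.LST, np.where(ok, t, np.nan))


def classification_predictors(composite: Composite) -> np.ndarray:
    """(10, rows, cols) predictor stack: 6 bands + NDVI, NDMI, NBR, MNDWI."""
    layers = [composite.bands[i] for i in range(6)]
    layers += [ndvi(composite).values, ndmi(composite).values,
               nbr(composite).values, mndwi(composite).values]
    return np.stack(layers)


PREDICTOR_NAMES = tuple(BANDS) + ("ndvi", "ndmi", "nbr", "mndwi")
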