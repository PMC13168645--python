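"""Synthetic raised-bog landscapes and hydroclimate series with known truth.

The generator produces (a) monthly climate built as seasonal cycle + linear
trend + Gaussian noise, with the water balance ``cwb = ppt - pet`` holding
exactly by construction, and (b) an annual three-class landscape (Forest,
Bog, Grassland) in which bog pixels at the forest edge convert to forest with
a probability modulated by the standardized annual climatic water balance
(drier years convert faster).  Every downstream stage can therefore be tested
against exact ground truth.

All randomness flows from one master seed through named substreams, so the
same configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import RasterGrid
from .landcover import BOG, CLASS_CODES, FOREST, GRASSLAND, LandCoverMap
from .preprocess import BANDS, N_BANDS, QABitSpec, SceneStack, Sensor
from .trends import ClimateSeries

#: reflectance replacing cloud-contaminated observations
CLOUD_REFLECTANCE = 0.9


@dataclass
class ClassSpectrum:
    """Mean reflectance vector (6 bands, [0,1]) and mean thermal value (K)."""

    reflectance: tuple
    thermal_k: float

    def __post_init__(self):
        if len(self.reflectance) != N_BANDS:
            raise ValueError("class spectrum needs 6 reflectance means")
        if not all(0.0 <= r <= 1.0 for r in self.reflectance):
            raise ValueError("reflectance means must lie in [0, 1]")


# defaults are ecologically ordered: forest dark in red / bright in NIR and
# coolest; drying bog bright in SWIR and warmest; grassland intermediate.
DEFAULT_CLASS_SPECTRA = {
    FOREST: ClassSpectrum((0.03, 0.05, 0.04, 0.45, 0.15, 0.07), 295.0),
    BOG: ClassSpectrum((0.06, 0.09, 0.11, 0.22, 0.30, 0.25), 301.0),
    GRASSLAND: ClassSpectrum((0.05, 0.08, 0.08, 0.35, 0.22, 0.14), 298.0),
}


@dataclass
class MonthlyVariableConfig:
    """Seasonal cycle + linear trend + iid Gaussian noise for one variable."""

    mean: float
    seasonal_amplitude: float = 0.0
    peak_month: int = 7
    trend_per_year: float = 0.0
    noise_sd: float = 0.0


@dataclass
class ClimateConfig:
    ppt: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(65.0, 20.0, 7, -0.15, 8.0))
    pet: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(55.0, 40.0, 7, 0.20, 4.0))
    cwd: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(15.0, 12.0, 7, 0.10, 3.0))
    aet: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(45.0, 30.0, 7, 0.05, 3.0))
    runoff: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(20.0, 10.0, 1, -0.05, 4.0))
    tmean: MonthlyVariableConfig = field(default_factory=lambda: MonthlyVariableConfig(8.0, 9.0, 7, 0.04, 0.8))


@dataclass
class SimulationConfig:
    grid_rows: int = 100
    grid_cols: int = 100
    pixel_size_m: float = 30.0
    years: tuple = tuple(range(1984, 2025))
    class_spectra: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SPECTRA))
    spectral_noise_sd: float = 0.02
    thermal_noise_sd: float = 0.5
    thermal_anomaly_scale: float = 1.0
    encroachment_base_rate: float = 0.05
    deficit_sensitivity: float = 0.5
    grassland_conversion_rate: float = 0.0   # optional grassland->forest process
    cloud_fraction: float = 0.0
    initial_shares: tuple = (0.55, 0.35, 0.10)   # forest, bog, grassland
    scenes_per_year: int = 1
    scene_doys: tuple = (170, 185, 215)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    seed: int = 0

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        self.years = years
        for name in ("encroachment_base_rate", "grassland_conversion_rate", "cloud_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.initial_shares) - 1.0) > 1e-9:
            raise ValueError("initial class shares must sum to 1")
        if self.scenes_per_year < 1 or self.scenes_per_year > len(self.scene_doys):
            raise ValueError("scenes_per_year must be between 1 and len(scene_doys)")

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid.square(self.grid_rows, self.grid_cols, self.pixel_size_m)


@dataclass
class TruthRecord:
    year: int
    true_map: LandCoverMap
    n_converted_pixels: int


@dataclass
class LandscapeYear:
    """One simulated year: the acquisitions and the ground truth."""

    year: int
    scenes: list
    truth: TruthRecord

    @property
    def scene(self) -> SceneStack:
        return self.scenes[0]


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tags))


# ---------------------------------------------------------------------------
# climate


def simulate_climate(config: SimulationConfig, seed: int | None = None) -> ClimateSeries:
    """Monthly PPT/PET/CWD/AET/runoff/temperature for the configured years.

    Each variable is seasonal cycle + linear trend (per whole year, so annual
    means drift at exactly the configured rate) + iid Gaussian noise.
    """
    years = config.years
    if len(years) < 2:
        raise ValueError("need at least 2 years of climate")
    rng = _substream(config.seed if seed is None else seed, 1)
    months = np.arange(1, 13)
    records = {"year": [], "month": []}
    for y in years:
        records["year"].extend([y] * 12)
        records["month"].extend(months.tolist())
    table = pd.DataFrame(records)

    year_offset = table["year"].to_numpy() - years[0]
    month = table["month"].to_numpy()
    for name in ("ppt", "pet", "cwd", "aet", "runoff", "tmean"):
        vc: MonthlyVariableConfig = getattr(config.climate, name)
        cycle = vc.mean + vc.seasonal_amplitude * np.cos(
            2.0 * np.pi * (month - vc.peak_month) / 12.0)
        noise = rng.normal(0.0, vc.noise_sd, size=len(table)) if vc.noise_sd > 0 else 0.0
        table[name] = cycle + vc.trend_per_year * year_offset + noise
    return ClimateSeries(table)


def _standardized_cwb(climate: ClimateSeries, years) -> np.ndarray:
    """Standardized annual (JJA) climatic water balance for the given years."""
    t = climate.table
    jja = t[t["month"].isin((6, 7, 8))].groupby("year")["cwb"].sum()
    values = np.array([jja.loc[y] for y in years], dtype=np.float64)
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# landscape


def _initial_truth_map(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = config.grid_rows, config.grid_cols
    n = rows * cols
    classes = np.full((rows, cols), FOREST, dtype=np.int16)

    # contiguous central bog: filled disk sized to the bog share
    bog_share = config.initial_shares[1]
    rr, cc = np.indices((rows, cols))
    radius = np.sqrt(bog_share * n / np.pi)
    dist = np.hypot(rr - (rows - 1) / 2.0, cc - (cols - 1) / 2.0)
    classes[dist <= radius] = BOG

    # grassland: random rectangular patches in the forest matrix
    grass_target = int(round(config.initial_shares[2] * n))
    guard = 0
    while (classes == GRASSLAND).sum() < grass_target and guard < 10_000:
        guard += 1
        h = int(rng.integers(3, max(4, rows // 8)))
        w = int(rng.integers(3, max(4, cols // 8)))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        block = classes[r0:r0 + h, c0:c0 + w]
        block[block == FOREST] = GRASSLAND
    return classes


_EIGHT = np.ones((3, 3), dtype=bool)


def eligible_bog_edge(classes: np.ndarray) -> np.ndarray:
    """Bog pixels 8-adjacent to at least one forest pixel."""
    forest_neighbour = ndimage.binary_dilation(classes == FOREST, structure=_EIGHT)
    return (classes == BOG) & forest_neighbour


def conversion_probability(base_rate: float, deficit_sensitivity: float,
                           cwb_z: float) -> float:
    """clamp(base * (1 + sensitivity * standardized deficit), 0, 1).

    The deficit is the *negative* standardized water balance, so dry years
    (cwb_z < 0) raise the probability.
    """
    return float(np.clip(base_rate * (1.0 + deficit_sensitivity * (-cwb_z)), 0.0, 1.0))


def simulate_landscape(config: SimulationConfig, climate: ClimateSeries,
                       seed: int | None = None) -> list:
    """Generate per-year scene stacks plus ground-truth maps.

    Year 1 holds the initial mosaic; in each later year every eligible
    bog-edge pixel converts to forest with the climate-modulated probability,
    and (optionally) grassland converts at ``grassland_conversion_rate``.
    """
    if not set(config.years) <= set(climate.years.tolist()):
        raise ValueError("climate does not cover all requested years")
    master = config.seed if seed is None else seed
    rng_init = _substream(master, 2)
    grid = config.grid

    cwb_z = _standardized_cwb(climate, config.years)
    jja_t = climate.table[climate.table["month"].isin((6, 7, 8))].groupby("year")["tmean"].mean()
    t_anom = np.array([jja_t.loc[y] for y in config.years]) - np.mean(
        [jja_t.loc[y] for y in config.years])

    classes = _initial_truth_map(config, rng_init)
    out = []
    for k, year in enumerate(config.years):
        n_converted = 0
        if k > 0:
            rng_year = _substream(master, 3, k)
            p = conversion_probability(config.encroachment_base_rate,
                                       config.deficit_sensitivity, cwb_z[k])
            edge = eligible_bog_edge(classes)
            convert = edge & (rng_year.random(classes.shape) < p)
            n_converted = int(convert.sum())
            classes = classes.copy()
            classes[convert] = FOREST
            if config.grassland_conversion_rate > 0:
                g_edge = (classes == GRASSLAND) & ndimage.binary_dilation(
                    classes == FOREST, structure=_EIGHT)
                g_convert = g_edge & (rng_year.random(classes.shape)
                                      < config.grassland_conversion_rate)
                classes[g_convert] = FOREST

        truth = TruthRecord(year, LandCoverMap(year, classes.copy(), grid), n_converted)
        scenes = []
        for s in range(config.scenes_per_year):
            rng_scene = _substream(master, 4, k, s)
            scene = _render_scene(config, grid, classes, year,
                                  config.scene_doys[s], float(t_anom[k]), rng_scene)
            if config.cloud_fraction > 0:
                scene = inject_clouds(scene, config.cloud_fraction,
                                      rng=_substream(master, 5, k, s))
            scenes.append(scene)
        out.append(LandscapeYear(year, scenes, truth))
    return out


def _render_scene(config, grid, classes, year, doy, thermal_anomaly, rng) -> SceneStack:
    rows, cols = grid.shape
    bands = np.empty((N_BANDS, rows, cols), dtype=np.float64)
    thermal = np.empty((rows, cols), dtype=np.float64)
    for code in CLASS_CODES:
        mask = classes == code
        spec = config.class_spectra[code]
        for b in range(N_BANDS):
            bands[b][mask] = spec.reflectance[b]
        thermal[mask] = spec.thermal_k + config.thermal_anomaly_scale * thermal_anomaly
    if config.spectral_noise_sd > 0:
        bands += rng.normal(0.0, config.spectral_noise_sd, size=bands.shape)
    if config.thermal_noise_sd > 0:
        thermal += rng.normal(0.0, config.thermal_noise_sd, size=thermal.shape)
    qa = np.zeros((rows, cols), dtype=np.uint16)
    return SceneStack(year=year, acquisition_doy=doy, sensor_id=Sensor.SYNTHETIC,
                      bands=bands, thermal=thermal, qa=qa, grid=grid)


# ---------------------------------------------------------------------------
# clouds


def inject_clouds(scene: SceneStack, cloud_fraction: float,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  spec: QABitSpec | None = None) -> SceneStack:
    """Flag ~``cloud_fraction`` of pixels as cloud with random circular masks.

    The flagged count is exact up to integer quantisation of the target
    fraction; reflectance under clouds is replaced by a bright constant.
    """
    if not 0.0 <= cloud_fraction <= 1.0:
        raise ValueError("cloud_fraction must lie in [0, 1]")
    spec = spec or QABitSpec()
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows, cols = scene.grid.shape
    target = int(round(cloud_fraction * rows * cols))

    mask = np.zeros((rows, cols), dtype=bool)
    if target > 0:
        rr, cc = np.indices((rows, cols))
        max_radius = max(3.0, min(rows, cols) / 6.0)
        guard = 0
        while mask.sum() < target and guard < 10_000:
            guard += 1
            cy = rng.uniform(0, rows)
            cx = rng.uniform(0, cols)
            radius = rng.uniform(2.0, max_radius)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2
        excess = int(mask.sum()) - target
        if excess > 0:   # trim random flagged pixels back to the exact target
            flat = np.flatnonzero(mask)
            drop = rng.choice(flat, size=excess, replace=False)
            mask.ravel()[drop] = False

    qa = scene.qa.copy()
    qa[mask] |= 1 << spec.cloud
    bands = scene.bands.copy()
    bands[:, mask] = CLOUD_REFLECTANCE
    return SceneStack(year=scene.year, acquisition_doy=scene.acquisition_doy,
                      sensor_id=scene.sensor_id, bands=bands,
                      thermal=scene.thermal.copy(), qa=qa, grid=scene.grid,
                      saturation=scene.saturation)
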