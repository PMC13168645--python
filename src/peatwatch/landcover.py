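"""Land-cover classification and accounting.

Two-stage training (maximum-likelihood seed classification of reference years,
stable-pixel intersection, balanced point sampling), Random-Forest
classification of every annual composite, hold-out accuracy assessment,
temporal majority filtering, class-area accounting and Markov transition
estimation for a three-class landscape {Forest, Bog, Grassland}.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grid import RasterGrid, require_same_grid
from .indices import PREDICTOR_NAMES, classification_predictors
from .preprocess import Composite

log = logging.getLogger(__name__)

NODATA = 0
FOREST, BOG, GRASSLAND = 1, 2, 3
CLASS_CODES = (FOREST, BOG, GRASSLAND)
CLASS_NAMES = {FOREST: "Forest", BOG: "Bog", GRASSLAND: "Grassland"}
N_PREDICTORS = len(PREDICTOR_NAMES)


class TransitionMode(str, enum.Enum):
    START_TO_END = "start_to_end"
    POOLED_ANNUAL = "pooled_annual"


@dataclass
class LandCoverMap:
    """Categorical raster coded {1 Forest, 2 Bog, 3 Grassland, 0 nodata}."""

    year: int
    classes: np.ndarray
    grid: RasterGrid

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.shape != self.grid.shape:
            raise ValueError("class raster does not match grid")
        codes = np.unique(self.classes)
        bad = set(codes.tolist()) - ({NODATA} | set(CLASS_CODES))
        if bad:
            raise ValueError(f"unknown class codes present: {sorted(bad)}")

    def mask(self, code: int) -> np.ndarray:
        return self.classes == code

    @property
    def valid_mask(self) -> np.ndarray:
        return self.classes != NODATA


@dataclass
class TrainingSet:
    """Pooled, balanced training points with their predictor vectors."""

    points: pd.DataFrame  # columns: row, col, year, label, <10 predictors>

    def __post_init__(self):
        required = {"row", "col", "year", "label", *PREDICTOR_NAMES}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"training table missing columns: {sorted(missing)}")

    @property
    def X(self) -> np.ndarray:
        return self.points[list(PREDICTOR_NAMES)].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.points["label"].to_numpy(dtype=np.int64)

    @property
    def class_counts(self) -> dict:
        return self.points["label"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AccuracyReport:
    confusion_matrix: np.ndarray     # rows = reference, cols = predicted
    labels: tuple
    overall_accuracy: float
    kappa: float
    per_class: pd.DataFrame          # columns: label, ua, pa, type1, type2, f1

    def f1(self, label: int) -> float:
        return float(self.per_class.set_index("label").loc[label, "f1"])


@dataclass
class TransitionMatrix:
    matrix: np.ndarray               # 3x3 row-stochastic; NaN row = empty start class
    counts: np.ndarray
    mode: TransitionMode
    labels: tuple = CLASS_CODES

    def prob(self, src: int, dst: int) -> float:
        return float(self.matrix[self.labels.index(src), self.labels.index(dst)])


# ---------------------------------------------------------------------------
# maximum-likelihood seed classification


def class_statistics_from_samples(predictors: np.ndarray, reference: LandCoverMap,
                                  n_per_class: int = 500, seed: int = 0) -> dict:
    """Per-class mean vector and covariance of the predictor stack, sampled at
    reference-map pixels.  Stands in for user-drawn seed polygons in tests."""
    rng = np.random.default_rng(seed)
    finite = np.isfinite(predictors).all(axis=0)
    stats = {}
    for code in CLASS_CODES:
        rows, cols = np.nonzero(reference.mask(code) & finite)
        if rows.size < N_PREDICTORS + 1:
            raise ValueError(f"too few pixels to estimate statistics for class {code}")
        take = rng.choice(rows.size, size=min(n_per_class, rows.size), replace=False)
        X = predictors[:, rows[take], cols[take]].T
        stats[code] = (X.mean(axis=0), np.cov(X, rowvar=False))
    return stats


def maximum_likelihood_classify(composite: Composite, class_stats: dict,
                                ridge: float = 1e-9) -> LandCoverMap:
    """Per-pixel argmax of the Gaussian log-likelihood over the 10 predictors.

    Ties go to the lowest class code; a singular covariance is
    ridge-regularized with a logged warning.
    """
    predictors = classification_predictors(composite)
    return _ml_classify_stack(predictors, composite.grid, composite.year,
                              class_stats, ridge)


def _ml_classify_stack(predictors: np.ndarray, grid: RasterGrid, year: int,
                       class_stats: dict, ridge: float = 1e-9) -> LandCoverMap:
    finite = np.isfinite(predictors).all(axis=0)
    X = predictors[:, finite].T                      # (n_valid, p)
    codes = sorted(class_stats)
    loglik = np.full((len(codes), X.shape[0]), -np.inf)
    for k, code in enumerate(codes):
        mean, cov = class_stats[code]
        mean = np.asarray(mean, dtype=np.float64)
        cov = np.asarray(cov, dtype=np.float64)
        sign, logdet = np.linalg.slogdet(cov)
        eps = ridge
        while sign <= 0 or not np.isfinite(logdet):
            log.warning("singular covariance for class %s; adding ridge %g", code, eps)
            cov = cov + eps * np.eye(cov.shape[0])
            sign, logdet = np.linalg.slogdet(cov)
            eps *= 10.0
        diff = X - mean
        maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
        loglik[k] = -0.5 * (logdet + maha)
    # argmax with ties to the lowest code: argmax returns the first maximum
    # and codes are sorted ascending
    best = np.argmax(loglik, axis=0)
    classes = np.zeros(grid.shape, dtype=np.int16)
    classes[finite] = np.asarray(codes, dtype=np.int16)[best]
    return LandCoverMap(year=year, classes=classes, grid=grid)


# ---------------------------------------------------------------------------
# stable pixels and training samples


def stable_pixel_mask(reference_maps) -> dict:
    """Per-class masks of pixels classified identically in every reference year."""
    if len(reference_maps) < 2:
        raise ValueError("need at least two reference-year maps")
    require_same_grid(*[m.grid for m in reference_maps])
    stacked = np.stack([m.classes for m in reference_maps])
    return {code: (stacked == code).all(axis=0) for code in CLASS_CODES}


def sample_balanced_training(stable_masks: dict, n_per_class: int,
                             reference_years, composites: dict,
                             seed: int = 0) -> TrainingSet:
    """Sample ``n_per_class`` stable point locations per class (without
    replacement) and extract predictor vectors at every reference year.

    Rows are pooled over years, so each class contributes
    ``n_per_class * len(reference_years)`` rows.
    """
    rng = np.random.default_rng(seed)
    predictor_stacks = {y: classification_predictors(composites[y]) for y in reference_years}
    all_finite = np.logical_and.reduce(
        [np.isfinite(predictor_stacks[y]).all(axis=0) for y in reference_years])

    records = []
    for code in CLASS_CODES:
        rows, cols = np.nonzero(stable_masks[code] & all_finite)
        if rows.size < n_per_class:
            raise ValueError(
                f"class {CLASS_NAMES[code]} has only {rows.size} usable stable pixels, "
                f"need {n_per_class}")
        take = rng.choice(rows.size, size=n_per_class, replace=False)
        for y in reference_years:
            vecs = predictor_stacks[y][:, rows[take], cols[take]].T
            df = pd.DataFrame(vecs, columns=list(PREDICTOR_NAMES))
            df.insert(0, "label", code)
            df.insert(0, "year", y)
            df.insert(0, "col", cols[take])
            df.insert(0, "row", rows[take])
            records.append(df)
    return TrainingSet(pd.concat(records, ignore_index=True))


def split_train_validation(training_set: TrainingSet, fraction: float = 0.75,
                           seed: int = 0):
    """Uniform per-row random split: draw u~U(0,1), train iff u < fraction."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.random(len(training_set))
    in_train = u < fraction
    return (TrainingSet(training_set.points[in_train].reset_index(drop=True)),
            TrainingSet(training_set.points[~in_train].reset_index(drop=True)))


# ---------------------------------------------------------------------------
# random forest


def train_random_forest(train: TrainingSet, n_trees: int = 200, seed: int = 0,
                        **kwargs) -> RandomForestClassifier:
    """Seeded Random Forest over the 10 predictors (sqrt-p feature subsampling)."""
    y = train.y
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed,
        n_jobs=1, **kwargs)
    clf.fit(train.X, y)
    return clf


def classify_with_forest(clf, composite: Composite) -> LandCoverMap:
    predictors = classification_predictors(composite)
    finite = np.isfinite(predictors).all(axis=0)
    classes = np.zeros(composite.grid.shape, dtype=np.int16)
    if finite.any():
        classes[finite] = clf.predict(predictors[:, finite].T).astype(np.int16)
    return LandCoverMap(year=composite.year, classes=classes, grid=composite.grid)


# ---------------------------------------------------------------------------
# accuracy


def confusion_matrix(reference: np.ndarray, predicted: np.ndarray,
                     labels=CLASS_CODES) -> np.ndarray:
    """Counts with rows = reference, columns = predicted."""
    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    index = {lab: i for i, lab in enumerate(labels)}
    for r, p in zip(np.asarray(reference).ravel(), np.asarray(predicted).ravel()):
        cm[index[int(r)], index[int(p)]] += 1
    return cm


def accuracy_report_from_confusion(cm: np.ndarray,
                                   labels=CLASS_CODES) -> AccuracyReport:
    cm = np.asarray(cm, dtype=np.int64)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm).astype(np.float64)
    oa = diag.sum() / n
    row = cm.sum(axis=1).astype(np.float64)   # reference totals
    col = cm.sum(axis=0).astype(np.float64)   # prediction totals
    pe = (row * col).sum() / (n * n)
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0

    rows = []
    for i, lab in enumerate(labels):
        ua = diag[i] / col[i] if col[i] > 0 else np.nan   # user's acc. = precision
        pa = diag[i] / row[i] if row[i] > 0 else np.nan   # producer's acc. = recall
        f1 = f1_from_errors(1.0 - ua, 1.0 - pa) if np.isfinite(ua) and np.isfinite(pa) else np.nan
        rows.append({"label": lab, "ua": ua, "pa": pa,
                     "type1": 1.0 - ua, "type2": 1.0 - pa, "f1": f1})
    return AccuracyReport(cm, tuple(labels), float(oa), float(kappa),
                          pd.DataFrame(rows))


def f1_from_errors(type1: float, type2: float) -> float:
    """F1 from commission (1-UA) and omission (1-PA) error rates."""
    ua, pa = 1.0 - type1, 1.0 - type2
    if ua + pa == 0.0:
        return 0.0
    return 2.0 * ua * pa / (ua + pa)


def assess_accuracy(clf, validation: TrainingSet,
                    n_stratified_per_class: int = 1500,
                    seed: int = 0) -> AccuracyReport:
    """Confusion-matrix accuracy on a stratified subset of the validation rows.

    ``n_stratified_per_class`` rows are drawn per class; a class with fewer
    rows contributes all of them (logged).  An empty class is an error.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for code in CLASS_CODES:
        cls = validation.points[validation.points.label == code]
        if cls.empty:
            raise ValueError(f"validation set has no rows for class {CLASS_NAMES[code]}")
        if len(cls) < n_stratified_per_class:
            log.info("class %s: only %d validation rows (< %d), using all",
                     CLASS_NAMES[code], len(cls), n_stratified_per_class)
            parts.append(cls)
        else:
            take = rng.choice(len(cls), size=n_stratified_per_class, replace=False)
            parts.append(cls.iloc[take])
    subset = TrainingSet(pd.concat(parts, ignore_index=True))
    predicted = clf.predict(subset.X)
    cm = confusion_matrix(subset.y, predicted)
    return accuracy_report_from_confusion(cm)


# ---------------------------------------------------------------------------
# temporal filter, areas, transitions


def temporal_majority_filter(annual_maps, window: int = 5):
    """Pixel-wise modal class over a centered multi-year window.

    The window is truncated at the series ends; ties (including two-way ties
    in truncated edge windows) keep the center-year label.  Nodata pixels stay
    nodata and never vote.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    require_same_grid(*[m.grid for m in annual_maps])
    stacked = np.stack([m.classes for m in annual_maps])      # (t, r, c)
    half = window // 2
    t = stacked.shape[0]
    out = []
    for i, m in enumerate(annual_maps):
        lo, hi = max(0, i - half), min(t, i + half + 1)
        win = stacked[lo:hi]
        counts = np.stack([(win == code).sum(axis=0) for code in CLASS_CODES])
        best = np.max(counts, axis=0)
        center = stacked[i]
        center_counts = np.choose(np.clip(center - 1, 0, 2), counts)
        # tie (or center participates in the max) -> keep the center label
        keep_center = (center != NODATA) & (center_counts == best)
        modal = np.asarray(CLASS_CODES, dtype=np.int16)[np.argmax(counts, axis=0)]
        filtered = np.where(keep_center, center, modal).astype(np.int16)
        filtered[center == NODATA] = NODATA
        out.append(LandCoverMap(year=m.year, classes=filtered, grid=m.grid))
    return out


def class_areas(lc_map: LandCoverMap, pixel_area_ha: float | None = None) -> pd.DataFrame:
    """Per-class hectares and percent of the classified area for one map."""
    if pixel_area_ha is None:
        pixel_area_ha = lc_map.grid.pixel_area_ha
    counts = {code: int(lc_map.mask(code).sum()) for code in CLASS_CODES}
    total = sum(counts.values())
    rows = []
    for code in CLASS_CODES:
        area = counts[code] * pixel_area_ha
        rows.append({"year": lc_map.year, "class": CLASS_NAMES[code],
                     "code": code, "pixels": counts[code], "area_ha": area,
                     "percent": 100.0 * counts[code] / total if total else np.nan})
    return pd.DataFrame(rows)


def area_table(annual_maps, pixel_area_ha: float | None = None) -> pd.DataFrame:
    return pd.concat([class_areas(m, pixel_area_ha) for m in annual_maps],
                     ignore_index=True)


def shares_from_areas(areas_ha: dict) -> dict:
    """Percent share of each class from a {class: hectares} mapping."""
    total = float(sum(areas_ha.values()))
    if total <= 0:
        raise ValueError("total area must be positive")
    return {k: 100.0 * v / total for k, v in areas_ha.items()}


def transition_matrix(first_map: LandCoverMap = None, last_map: LandCoverMap = None,
                      annual_maps=None,
                      mode: TransitionMode = TransitionMode.START_TO_END) -> TransitionMatrix:
    """Row-stochastic class-transition matrix.

    ``start_to_end`` (default): entry (i, j) is the fraction of first-year
    class-i pixels classified j in the final year.  ``pooled_annual``: pair
    frequencies pooled over all consecutive-year map pairs.  Empty start
    classes yield a NaN row, flagged via a logged warning.
    """
    mode = TransitionMode(mode)
    if mode == TransitionMode.START_TO_END:
        if first_map is None or last_map is None:
            if annual_maps is None or len(annual_maps) < 2:
                raise ValueError("start_to_end mode needs a first and last map")
            first_map, last_map = annual_maps[0], annual_maps[-1]
        pairs = [(first_map, last_map)]
    else:
        if annual_maps is None or len(annual_maps) < 2:
            raise ValueError("pooled_annual mode needs >=2 annual maps")
        pairs = list(zip(annual_maps[:-1], annual_maps[1:]))

    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in pairs:
        require_same_grid(a.grid, b.grid)
        both = a.valid_mask & b.valid_mask
        for i, src in enumerate(CLASS_CODES):
            src_mask = both & (a.classes == src)
            for j, dst in enumerate(CLASS_CODES):
                counts[i, j] += int((b.classes[src_mask] == dst).sum())

    row_sums = counts.sum(axis=1, keepdims=True).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / row_sums
    for i, code in enumerate(CLASS_CODES):
        if row_sums[i, 0] == 0:
            log.warning("transition matrix: empty start class %s", CLASS_NAMES[code])
            matrix[i] = np.nan
    return TransitionMatrix(matrix, counts, mode)
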