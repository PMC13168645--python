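"""End-minus-start change mapping: delta raster, change thresholding,
distributional summaries and contiguous-patch statistics."""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure


class ThresholdRule(str, enum.Enum):
    ABS_VALUE = "abs_value"
    STD_MULTIPLE = "std_multiple"


@dataclass
class ChangeSummary:
    threshold_value: float
    changed_area_ha: float
    improved_area_ha: float
    improved_percent: float     # of the changed area
    degraded_area_ha: float
    degraded_percent: float
    mean: float
    median: float
    iqr: float
    percentiles: dict           # {2, 10, 90, 98} -> value
    min: float
    max: float


@dataclass
class PatchTable:
    patches: pd.DataFrame       # id, sign, pixels, area_ha
    connectivity: int

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def largest_patch_ha(self) -> float:
        return float(self.patches.area_ha.max()) if len(self.patches) else 0.0

    @property
    def total_area_ha(self) -> float:
        return float(self.patches.area_ha.sum())


def delta_rsei(rsei_end: np.ndarray, rsei_start: np.ndarray) -> np.ndarray:
    """Per-pixel end - start difference; nodata wherever either is missing."""
    a = np.asarray(rsei_end, dtype=np.float64)
    b = np.asarray(rsei_start, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between end and start layers")
    return a - b


def resolve_threshold(delta: np.ndarray, rule: ThresholdRule | str,
                      value: float | None = None) -> float:
    rule = ThresholdRule(rule)
    if rule == ThresholdRule.ABS_VALUE:
        return float(0.02 if value is None else value)
    m = 0.5 if value is None else value
    return float(m * np.nanstd(delta))


def threshold_change(delta: np.ndarray, rule: ThresholdRule | str = ThresholdRule.ABS_VALUE,
                     value: float | None = None):
    """Changed mask: |delta| > threshold.  Returns (mask, threshold_value)."""
    threshold = resolve_threshold(delta, rule, value)
    d = np.asarray(delta, dtype=np.float64)
    mask = np.isfinite(d) & (np.abs(d) > threshold)
    return mask, threshold


def summarize_delta(delta: np.ndarray, changed_mask: np.ndarray,
                    pixel_area_ha: float, threshold_value: float = float("nan")) -> ChangeSummary:
    """Distribution of the delta over valid pixels plus improved/degraded areas
    within the changed mask.  Percentiles use linear interpolation."""
    d = np.asarray(delta, dtype=np.float64)
    valid = np.isfinite(d)
    if not valid.any():
        raise ValueError("no valid pixels to summarize")
    vals = d[valid]
    q25, q75 = np.percentile(vals, [25, 75])
    pct = {p: float(np.percentile(vals, p)) for p in (2, 10, 90, 98)}

    improved = int((changed_mask & (d > 0)).sum())
    degraded = int((changed_mask & (d < 0)).sum())
    changed = improved + degraded   # a changed pixel has |d| > threshold > 0
    return ChangeSummary(
        threshold_value=threshold_value,
        changed_area_ha=changed * pixel_area_ha,
        improved_area_ha=improved * pixel_area_ha,
        improved_percent=100.0 * improved / changed if changed else float("nan"),
        degraded_area_ha=degraded * pixel_area_ha,
        degraded_percent=100.0 * degraded / changed if changed else float("nan"),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        iqr=float(q75 - q25),
        percentiles=pct,
        min=float(vals.min()),
        max=float(vals.max()),
    )


def label_patches(changed_mask: np.ndarray, delta: np.ndarray,
                  pixel_area_ha: float, connectivity: int = 8) -> PatchTable:
    """Connected components of same-sign changed pixels.

    ``connectivity`` is 4 or 8 (pixel neighbourhood).  Positive and negative
    patches are labelled separately so a patch never mixes signs.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    d = np.asarray(delta, dtype=np.float64)
    rows = []
    next_id = 1
    for sign, mask in (("+", changed_mask & (d > 0)), ("-", changed_mask & (d < 0))):
        labels, n = measure.label(mask, connectivity=skimage_conn, return_num=True)
        for lab in range(1, n + 1):
            pixels = int((labels == lab).sum())
            rows.append({"id": next_id, "sign": sign, "pixels": pixels,
                         "area_ha": pixels * pixel_area_ha})
            next_id += 1
    df = pd.DataFrame(rows, columns=["id", "sign", "pixels", "area_ha"])
    return PatchTable(df, connectivity)
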