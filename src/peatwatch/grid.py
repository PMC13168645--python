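"""Raster grid geometry shared by every raster in a run."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RasterGrid:
    """Rows/cols plus an affine geotransform and a CRS identifier.

    The transform is the GDAL-style 6-tuple ``(x0, dx, rx, y0, ry, dy)``:
    ``x = x0 + col*dx + row*rx`` and ``y = y0 + col*ry + row*dy``.
    """

    rows: int
    cols: int
    transform: tuple = field(default=(0.0, 30.0, 0.0, 0.0, 0.0, -30.0))
    crs: str = "EPSG:32633"

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple:
        return (self.rows, self.cols)

    @property
    def pixel_width_m(self) -> float:
        return abs(self.transform[1])

    @property
    def pixel_height_m(self) -> float:
        return abs(self.transform[5])

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_width_m * self.pixel_height_m / 10_000.0

    def same_as(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )

    @classmethod
    def square(cls, rows: int, cols: int, pixel_size_m: float = 30.0) -> "RasterGrid":
        return cls(rows, cols, (0.0, pixel_size_m, 0.0, 0.0, 0.0, -pixel_size_m))


def require_same_grid(*grids: RasterGrid) -> RasterGrid:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_as(g):
            raise ValueError(f"grid mismatch: {first} vs {g}")
    return first
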