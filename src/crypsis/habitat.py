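"""Habitat colouration from multi-band reflectance rasters.

Rasters hold red, green and blue surface-reflectance bands on a regular
grid.  Habitat colour at a sample point is the mean over pixels whose
centers fall within a buffer radius (default convention: center-in-circle).
Temporal stacks are averaged per pixel, and a two-period split supports
repeatability (ICC) estimation of habitat colour over time.

Rasters are written as plain multi-band TIFF with a JSON sidecar carrying
the geotransform and nodata sentinel (a world-file-like convention).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from crypsis.colorimetry import ColourVector

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class GeoTransform:
    """Maps pixel (row, col) centers to map coordinates.

    x = x_origin + (col + 0.5) * pixel_size_x
    y = y_origin - (row + 0.5) * pixel_size_y   (north-up raster)
    """

    x_origin: float
    y_origin: float
    pixel_size_x: float
    pixel_size_y: float
    geographic: bool = False  # True when units are degrees lon/lat

    def __post_init__(self) -> None:
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValueError("pixel sizes must be positive")

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.arange(shape[0]), np.arange(shape[1])
        x = self.x_origin + (cols + 0.5) * self.pixel_size_x
        y = self.y_origin - (rows + 0.5) * self.pixel_size_y
        return x, y


@dataclass
class HabitatRaster:
    """Red/green/blue reflectance bands on a shared grid."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    transform: GeoTransform
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("bands must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def bands(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue])

    def write(self, path: str | Path) -> None:
        """Write as multi-band TIFF plus a .json geotransform sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(
            path,
            self.bands.astype(np.float32),
            photometric="minisblack",
            planarconfig="separate",
        )
        meta = {
            "x_origin": self.transform.x_origin,
            "y_origin": self.transform.y_origin,
            "pixel_size_x": self.transform.pixel_size_x,
            "pixel_size_y": self.transform.pixel_size_y,
            "geographic": self.transform.geographic,
            "nodata": self.nodata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def read(cls, path: str | Path) -> "HabitatRaster":
        import tifffile

        path = Path(path)
        bands = tifffile.imread(path).astype(float)
        if bands.ndim != 3 or bands.shape[0] != 3:
            raise ValueError("expected a 3-band raster")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        nodata = meta.pop("nodata")
        return cls(bands[0], bands[1], bands[2], GeoTransform(**meta), nodata)


@dataclass
class SamplePoint:
    """A georeferenced sampling location (map units of the raster CRS)."""

    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for point {self.id!r}")


def temporal_mean(rasters: list[HabitatRaster]) -> HabitatRaster:
    """Per-pixel mean over a temporal raster stack, nodata-aware.

    A pixel is nodata in the output only when it is nodata in every input.
    """
    if not rasters:
        raise ValueError("empty raster list")
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape or r.transform != ref.transform:
            raise ValueError("rasters must share grid and geotransform")
    out_bands = []
    for band in ("red", "green", "blue"):
        stack = np.stack([getattr(r, band) for r in rasters])
        mask = np.stack([getattr(r, band) != r.nodata for r in rasters])
        counts = mask.sum(axis=0)
        sums = np.where(mask, stack, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), ref.nodata)
        out_bands.append(mean)
    return HabitatRaster(*out_bands, transform=ref.transform, nodata=ref.nodata)


def _buffer_mask(
    raster: HabitatRaster, point: SamplePoint, radius: float
) -> np.ndarray:
    x, y = raster.transform.pixel_centers(raster.shape)
    if raster.transform.geographic:
        # local metric scaling: 1 deg lat = R*pi/180 m; lon scaled by cos(lat)
        m_per_deg = EARTH_RADIUS_M * math.pi / 180.0
        dx = (x[None, :] - point.x) * m_per_deg * math.cos(math.radians(point.y))
        dy = (y[:, None] - point.y) * m_per_deg
    else:
        dx = x[None, :] - point.x
        dy = y[:, None] - point.y
    return dx**2 + dy**2 <= radius**2


def buffer_mean(
    raster: HabitatRaster, point: SamplePoint, radius: float
) -> ColourVector:
    """Mean colour over pixels whose centers fall within ``radius`` of the point.

    Falls back to the pixel containing the point when no center qualifies
    (radius smaller than half the pixel spacing).  For geographic rasters
    the radius is in meters and degrees are converted by local metric
    scaling (cos-latitude).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    t = raster.transform
    col = int((point.x - t.x_origin) / t.pixel_size_x)
    row = int((t.y_origin - point.y) / t.pixel_size_y)
    if not (0 <= row < raster.shape[0] and 0 <= col < raster.shape[1]):
        raise ValueError(f"point {point.id!r} outside raster extent")
    mask = _buffer_mask(raster, point, radius)
    if not mask.any():
        mask = np.zeros(raster.shape, dtype=bool)
        mask[row, col] = True
    channels = []
    for band in (raster.red, raster.green, raster.blue):
        vals = band[mask]
        vals = vals[vals != raster.nodata]
        if vals.size == 0:
            raise ValueError(f"all pixels nodata in buffer of point {point.id!r}")
        channels.append(float(vals.mean()))
    return ColourVector(*channels)


def split_period_repeatability(
    group_a: list[HabitatRaster],
    group_b: list[HabitatRaster],
    points: list[SamplePoint],
    radius: float,
) -> list[tuple[ColourVector, ColourVector]]:
    """Paired habitat colours from two temporal groups, for downstream ICC.

    Mirrors a two-period repeatability design: each group is temporally
    averaged, then the buffer mean is extracted per point from each.
    """
    if not group_a or not group_b:
        raise ValueError("both period groups must be non-empty")
    mean_a, mean_b = temporal_mean(group_a), temporal_mean(group_b)
    return [
        (buffer_mean(mean_a, p, radius), buffer_mean(mean_b, p, radius))
        for p in points
    ]
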