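"""Multiband raster model, GeoTIFF I/O and smoothed differential operators.

The raster model is deliberately narrow: north-up, square-pixel grids with an
affine (scale + offset) geotransform, area pixels whose centers sit at
half-integer offsets from the origin. All curve/image sampling downstream is
bilinear at world coordinates.

GeoTIFF files are written with ``tifffile``: the pixel scale and tiepoint go
into the standard GeoTIFF tags (33550/33922) and band names, nodata and CRS
identifier into a JSON ImageDescription, so files round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

#: Canonical 14-band configuration used for habitat signatures.
SENTINEL2_BANDS = (
    "AOT", "B01", "B02", "B03", "B04", "B05", "B06",
    "B07", "B08", "B8A", "B09", "B11", "B12", "WVP",
)

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class UnsupportedGeometryError(ValueError):
    """Raised for rotated or non-square-pixel geotransforms."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform: world = origin + pixel_size * (col, -row)."""

    origin_x: float
    origin_y: float
    pixel_size_x: float
    pixel_size_y: float

    def __post_init__(self) -> None:
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise UnsupportedGeometryError(
                f"pixel sizes must be positive, got "
                f"({self.pixel_size_x}, {self.pixel_size_y})"
            )

    def world_to_pixel(self, x, y):
        """Continuous (col, row); pixel (0, 0) spans [origin, origin + size)."""
        col = (np.asarray(x, dtype=float) - self.origin_x) / self.pixel_size_x
        row = (self.origin_y - np.asarray(y, dtype=float)) / self.pixel_size_y
        return col, row

    def pixel_to_world(self, col, row):
        x = self.origin_x + np.asarray(col, dtype=float) * self.pixel_size_x
        y = self.origin_y - np.asarray(row, dtype=float) * self.pixel_size_y
        return x, y

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size_x * self.pixel_size_y


@dataclass
class MultibandRaster:
    """Gridded multiband image with named bands and a shared geotransform."""

    bands: list[str]
    data: np.ndarray  # (n_bands, n_rows, n_cols)
    transform: GridTransform
    crs_id: str = "EPSG:32634"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (bands, rows, cols)")
        if len(self.bands) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.bands)} band names for {self.data.shape[0]} planes"
            )
        if len(set(self.bands)) != len(self.bands):
            raise ValueError("band names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.data[self.bands.index(name)]
        except ValueError:
            raise KeyError(f"band {name!r} not in raster (has {self.bands})") from None

    def scalar_field(self, name: str) -> "ScalarField":
        return ScalarField(
            data=self.band(name).astype(float),
            transform=self.transform,
            description=name,
        )

    def subset(self, bands: Sequence[str]) -> "MultibandRaster":
        idx = [self.bands.index(b) for b in bands]
        return replace(self, bands=list(bands), data=self.data[idx])

    def valid_mask(self, band_name: str | None = None) -> np.ndarray:
        """Boolean grid of pixels not equal to the nodata sentinel."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if band_name is not None:
            return self.band(band_name) != self.nodata
        return np.all(self.data != self.nodata, axis=0)


@dataclass
class ScalarField:
    """Single 2-D real grid sharing the raster transform; carries provenance."""

    data: np.ndarray
    transform: GridTransform
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ScalarField data must be 2-D")


# ---------------------------------------------------------------------------
# GeoTIFF I/O

def write_raster(raster: MultibandRaster, path: str | Path) -> None:
    t = raster.transform
    meta = {
        "bands": raster.bands,
        "crs_id": raster.crs_id,
        "nodata": raster.nodata,
    }
    tifffile.imwrite(
        str(path),
        raster.data,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_size_x, t.pixel_size_y, 0.0)),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
        ],
    )


def read_raster(
    path: str | Path, band_subset: Sequence[str] | None = None
) -> MultibandRaster:
    """Read a multiband GeoTIFF; optionally select/reorder bands.

    Raises FileNotFoundError for a missing path, KeyError for an absent
    requested band and UnsupportedGeometryError for rotated / non-square
    pixel geometries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tiepoint_tag = page.tags.get(_MODEL_TIEPOINT)
        if scale_tag is None or tiepoint_tag is None:
            raise UnsupportedGeometryError(f"{path}: missing geotransform tags")
        scale = tuple(scale_tag.value)
        tie = tuple(tiepoint_tag.value)
        desc = page.description

    if data.ndim == 2:
        data = data[None]
    sx, sy, _ = scale
    if tie[0] != 0 or tie[1] != 0:
        raise UnsupportedGeometryError(f"{path}: tiepoint not at raster origin")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    bands = meta.get("bands") or [f"band{i + 1}" for i in range(data.shape[0])]
    raster = MultibandRaster(
        bands=list(bands),
        data=data,
        transform=GridTransform(float(tie[3]), float(tie[4]), float(sx), float(sy)),
        crs_id=meta.get("crs_id", "unknown"),
        nodata=meta.get("nodata"),
    )
    if band_subset is not None:
        missing = [b for b in band_subset if b not in raster.bands]
        if missing:
            raise KeyError(f"requested bands absent from {path}: {missing}")
        raster = raster.subset(band_subset)
    return raster


def write_field(fieldv: ScalarField, path: str | Path) -> None:
    """Export a ScalarField as a single-band GeoTIFF (debugging aid)."""
    write_raster(
        MultibandRaster(
            bands=[fieldv.description or "field"],
            data=fieldv.data[None],
            transform=fieldv.transform,
        ),
        path,
    )


# ---------------------------------------------------------------------------
# Sampling and differential operators

def world_to_pixel(raster: MultibandRaster | ScalarField, xy) -> tuple:
    x, y = np.asarray(xy, dtype=float).T if np.ndim(xy) > 1 else xy
    return raster.transform.world_to_pixel(x, y)


def pixel_to_world(raster: MultibandRaster | ScalarField, colrow) -> tuple:
    col, row = np.asarray(colrow, dtype=float).T if np.ndim(colrow) > 1 else colrow
    return raster.transform.pixel_to_world(col, row)


def sample_bilinear(fieldv: ScalarField, xy) -> np.ndarray | float:
    """Bilinear interpolation at world point(s); pixel centers at +0.5 offsets.

    Raises ValueError when a query point falls outside the grid extent.
    """
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    col, row = fieldv.transform.world_to_pixel(pts[:, 0], pts[:, 1])
    # shift so integer coordinates land on pixel centers
    c = col - 0.5
    r = row - 0.5
    nrows, ncols = fieldv.data.shape
    if np.any(col < 0) or np.any(col > ncols) or np.any(row < 0) or np.any(row > nrows):
        raise ValueError("sample point outside raster extent")
    c = np.clip(c, 0.0, ncols - 1.0)
    r = np.clip(r, 0.0, nrows - 1.0)
    c0 = np.clip(np.floor(c).astype(int), 0, ncols - 2) if ncols > 1 else np.zeros_like(c, int)
    r0 = np.clip(np.floor(r).astype(int), 0, nrows - 2) if nrows > 1 else np.zeros_like(r, int)
    fc = c - c0
    fr = r - r0
    d = fieldv.data
    c1 = np.minimum(c0 + 1, ncols - 1)
    r1 = np.minimum(r0 + 1, nrows - 1)
    val = (
        d[r0, c0] * (1 - fr) * (1 - fc)
        + d[r0, c1] * (1 - fr) * fc
        + d[r1, c0] * fr * (1 - fc)
        + d[r1, c1] * fr * fc
    )
    return float(val[0]) if np.ndim(xy) == 1 else val


def gaussian_smooth(fieldv: ScalarField, sigma_px: float) -> ScalarField:
    """Discrete Gaussian convolution with reflect boundaries; mean-preserving."""
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    out = ndimage.gaussian_filter(fieldv.data, sigma=sigma_px, mode="reflect")
    return ScalarField(
        data=out,
        transform=fieldv.transform,
        description=f"gaussian({sigma_px})[{fieldv.description}]",
    )


def laplacian(fieldv: ScalarField) -> ScalarField:
    """5-point finite-difference Laplacian, replicate borders, h = pixel size."""
    d = fieldv.data
    if d.shape[0] < 3 or d.shape[1] < 3:
        raise ValueError(f"grid too small for Laplacian stencil: {d.shape}")
    padded = np.pad(d, 1, mode="edge")
    h2 = fieldv.transform.pixel_size_x * fieldv.transform.pixel_size_y
    lap = (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * d
    ) / h2
    return ScalarField(
        data=lap,
        transform=fieldv.transform,
        description=f"laplacian[{fieldv.description}]",
    )


def gradient(fieldv: ScalarField) -> tuple[ScalarField, ScalarField]:
    """Central-difference gradient (d/dx, d/dy) in world units (per meter)."""
    hx = fieldv.transform.pixel_size_x
    hy = fieldv.transform.pixel_size_y
    # rows increase southwards, so d/dy flips sign
    gy_row, gx_col = np.gradient(fieldv.data, hy, hx)
    return (
        ScalarField(gx_col, fieldv.transform, f"ddx[{fieldv.description}]"),
        ScalarField(-gy_row, fieldv.transform, f"ddy[{fieldv.description}]"),
    )
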