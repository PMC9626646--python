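"""Planar curves: GPS/GeoJSON ingestion, resampling, rasterization, geometry.

A :class:`PlanarCurve` is an ordered vertex list in projected world
coordinates (meters). Closed curves are normalized to simple,
counterclockwise rings with consecutive duplicates removed; open curves keep
their endpoints exactly.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LineString, Polygon
from shapely.validation import make_valid

from .crs import lonlat_to_utm, utm_to_lonlat
from .raster_io import MultibandRaster, GridTransform

DEFAULT_CLOSING_TOLERANCE_M = 30.0


class CurveError(ValueError):
    pass


@dataclass
class PlanarCurve:
    """Ordered vertex polyline/ring in world coordinates."""

    vertices: np.ndarray  # (n, 2)
    closed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        # drop consecutive duplicates
        if len(v) > 1:
            keep = np.ones(len(v), dtype=bool)
            keep[1:] = np.any(np.abs(np.diff(v, axis=0)) > 1e-12, axis=1)
            v = v[keep]
        if self.closed and len(v) > 1 and np.linalg.norm(v[0] - v[-1]) < 1e-9:
            v = v[:-1]
        self.vertices = v
        n_min = 3 if self.closed else 2
        if len(v) < n_min:
            raise CurveError(
                f"{'closed' if self.closed else 'open'} curve needs >= {n_min} "
                f"vertices, got {len(v)}"
            )
        if self.closed and _signed_area(v) < 0:
            self.vertices = v[::-1].copy()

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def segments(self) -> np.ndarray:
        """Edge vectors; for closed curves includes the wrap-around edge."""
        v = self.vertices
        if self.closed:
            return np.diff(np.vstack([v, v[:1]]), axis=0)
        return np.diff(v, axis=0)

    @property
    def arclength(self) -> float:
        return float(np.linalg.norm(self.segments, axis=1).sum())

    def as_shapely(self):
        if self.closed:
            return Polygon(self.vertices)
        return LineString(self.vertices)

    def is_simple(self) -> bool:
        return self.as_shapely().is_valid if self.closed else True


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class RegionMask:
    """Boolean in-region grid aligned with a raster transform."""

    inside: np.ndarray
    transform: GridTransform
    outside_extent: bool = False

    @property
    def pixel_count(self) -> int:
        return int(self.inside.sum())

    @property
    def area_ha(self) -> float:
        return self.pixel_count * self.transform.pixel_area_m2 / 10_000.0


# ---------------------------------------------------------------------------
# geometry operations

def polygon_area_ha(curve: PlanarCurve) -> float:
    """Shoelace area in hectares; orientation-independent."""
    if not curve.closed:
        raise CurveError("area requires a closed curve")
    return abs(_signed_area(curve.vertices)) / 10_000.0


def resample_uniform(curve: PlanarCurve, spacing: float) -> PlanarCurve:
    """Redistribute vertices equally by arclength.

    Open curves keep both endpoints exactly; closed curves keep vertex 0 as
    the starting phase so repeated resampling at one spacing is idempotent.
    """
    if spacing <= 0:
        raise CurveError(f"spacing must be positive, got {spacing}")
    v = curve.vertices
    if curve.closed:
        pts = np.vstack([v, v[:1]])
    else:
        pts = v
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if curve.closed:
        n = max(3, int(round(total / spacing)))
        targets = np.arange(n) * (total / n)
    else:
        n_seg = max(1, int(round(total / spacing)))
        targets = np.linspace(0.0, total, n_seg + 1)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    if not curve.closed:
        out[0] = v[0]
        out[-1] = v[-1]
    return PlanarCurve(out, closed=curve.closed, label=curve.label)


def densify(curve: PlanarCurve, max_spacing: float) -> np.ndarray:
    """Vertex array with extra points so no edge exceeds ``max_spacing``.

    Unlike :func:`resample_uniform` the original vertices are all kept, so
    the densified polyline traces the input exactly.
    """
    if max_spacing <= 0:
        raise CurveError("max_spacing must be positive")
    v = curve.vertices
    pts = np.vstack([v, v[:1]]) if curve.closed else v
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        d = float(np.linalg.norm(b - a))
        k = max(1, int(math.ceil(d / max_spacing)))
        t = np.linspace(0.0, 1.0, k + 1)[1:]
        out.append(a[None] + t[:, None] * (b - a)[None])
    dense = np.vstack(out)
    return dense[:-1] if curve.closed else dense


def rasterize(curve: PlanarCurve, reference: MultibandRaster | GridTransform,
              shape: tuple[int, int] | None = None) -> RegionMask:
    """Pixel-center even-odd rasterization of a closed simple curve."""
    if not curve.closed:
        raise CurveError("rasterize requires a closed curve")
    if polygon_area_ha(curve) <= 0:
        raise CurveError("degenerate polygon with zero area")
    if isinstance(reference, GridTransform):
        if shape is None:
            raise ValueError("shape required when reference is a transform")
        transform, (nrows, ncols) = reference, shape
    else:
        transform, (nrows, ncols) = reference.transform, reference.shape

    inside = np.zeros((nrows, ncols), dtype=bool)
    col, row = transform.world_to_pixel(curve.vertices[:, 0], curve.vertices[:, 1])
    c0 = max(0, int(np.floor(col.min())) - 1)
    c1 = min(ncols, int(np.ceil(col.max())) + 1)
    r0 = max(0, int(np.floor(row.min())) - 1)
    r1 = min(nrows, int(np.ceil(row.max())) + 1)
    outside = c1 <= c0 or r1 <= r0
    if not outside:
        cc, rr = np.meshgrid(
            np.arange(c0, c1) + 0.5, np.arange(r0, r1) + 0.5
        )
        ring = np.column_stack([col, row])
        path = MplPath(np.vstack([ring, ring[:1]]), closed=True)
        hit = path.contains_points(
            np.column_stack([cc.ravel(), rr.ravel()])
        ).reshape(rr.shape)
        inside[r0:r1, c0:c1] = hit
        outside = not hit.any()
    return RegionMask(inside=inside, transform=transform, outside_extent=outside)


def clean_ring(vertices: np.ndarray, label: str = "") -> PlanarCurve:
    """Repair a possibly self-intersecting ring by keeping the largest simple
    ring; used after GPS ingestion and during curve evolution."""
    poly = Polygon(vertices)
    if not poly.is_valid:
        fixed = make_valid(poly)
        geoms = getattr(fixed, "geoms", [fixed])
        polys = [g for g in geoms if g.geom_type == "Polygon" and g.area > 0]
        if not polys:
            raise CurveError("ring degenerated under cleaning")
        poly = max(polys, key=lambda g: g.area)
    coords = np.asarray(poly.exterior.coords)[:-1]
    return PlanarCurve(coords, closed=True, label=label)


# ---------------------------------------------------------------------------
# GPX / GeoJSON I/O

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]

def read_gpx(
    path: str | Path,
    crs_id: str,
    closing_tolerance_m: float = DEFAULT_CLOSING_TOLERANCE_M,
) -> list[PlanarCurve]:
    """Read GPX 1.1 tracks into projected curves.

    Each track segment becomes one curve, projected from WGS84 into the
    declared UTM CRS; segments whose endpoints are within
    ``closing_tolerance_m`` are closed.
    """
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise CurveError(f"malformed GPX file {path}: {exc}") from exc

    curves: list[PlanarCurve] = []
    for trk in (el for el in root.iter() if _local(el.tag) == "trk"):
        name = next(
            (el.text or "" for el in trk.iter() if _local(el.tag) == "name"), ""
        )
        for seg in (el for el in trk.iter() if _local(el.tag) == "trkseg"):
            lonlat = [
                (float(pt.attrib["lon"]), float(pt.attrib["lat"]))
                for pt in seg
                if _local(pt.tag) == "trkpt"
            ]
            if len(lonlat) < 2:
                continue
            lon, lat = np.asarray(lonlat).T
            x, y = lonlat_to_utm(lon, lat, crs_id)
            v = np.column_stack([x, y])
            closed = (
                len(v) >= 4
                and np.linalg.norm(v[0] - v[-1]) <= closing_tolerance_m
            )
            if closed:
                if np.linalg.norm(v[0] - v[-1]) < 1e-9:
                    v = v[:-1]
                curves.append(clean_ring(v, label=name))
            else:
                curves.append(PlanarCurve(v, closed=False, label=name))
    if not curves:
        raise CurveError(f"no tracks with >= 2 points in {path}")
    return curves


def write_gpx(curves: list[PlanarCurve], path: str | Path, crs_id: str) -> None:
    """Write curves as GPX 1.1 tracks (closed curves repeat the first point)."""
    gpx = ET.Element(
        "gpx", version="1.1", creator="habcurve",
        xmlns="http://www.topografix.com/GPX/1/1",
    )
    for curve in curves:
        trk = ET.SubElement(gpx, "trk")
        ET.SubElement(trk, "name").text = curve.label
        seg = ET.SubElement(trk, "trkseg")
        v = curve.vertices
        if curve.closed:
            v = np.vstack([v, v[:1]])
        lon, lat = utm_to_lonlat(v[:, 0], v[:, 1], crs_id)
        for lo, la in zip(lon, lat):
            ET.SubElement(seg, "trkpt", lat=f"{la:.9f}", lon=f"{lo:.9f}")
    ET.ElementTree(gpx).write(str(path), xml_declaration=True, encoding="unicode")


def curves_to_geojson(curves: list[PlanarCurve]) -> dict:
    features = []
    for c in curves:
        if c.closed:
            ring = np.vstack([c.vertices, c.vertices[:1]]).tolist()
            geom = {"type": "Polygon", "coordinates": [ring]}
        else:
            geom = {"type": "LineString", "coordinates": c.vertices.tolist()}
        features.append(
            {"type": "Feature", "geometry": geom, "properties": {"label": c.label}}
        )
    return {"type": "FeatureCollection", "features": features}


def curves_from_geojson(obj: dict) -> list[PlanarCurve]:
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    out = []
    for f in feats:
        geom = f["geometry"] if f.get("type") == "Feature" else f
        label = (f.get("properties") or {}).get("label", "") if f.get("type") == "Feature" else ""
        if geom["type"] == "Polygon":
            out.append(PlanarCurve(np.asarray(geom["coordinates"][0]), closed=True, label=label))
        elif geom["type"] == "LineString":
            out.append(PlanarCurve(np.asarray(geom["coordinates"]), closed=False, label=label))
        else:
            raise CurveError(f"unsupported geometry type {geom['type']}")
    return out


def write_geojson(curves: list[PlanarCurve], path: str | Path) -> None:
    Path(path).write_text(json.dumps(curves_to_geojson(curves)))


def read_geojson(path: str | Path) -> list[PlanarCurve]:
    return curves_from_geojson(json.loads(Path(path).read_text()))
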