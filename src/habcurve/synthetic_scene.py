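"""Synthetic multiband scene generator with ground-truth boundaries.

Scenes emulate the statistical structure of 10 m L2A imagery over forest
habitats: patches are smooth random blobs with per-band mean reflectance and
within-patch variation, plus a texture term that separates structurally
heterogeneous ("natural") stands from smooth, periodically planted
("plantation") stands, plus sensor noise. Jittered GPS-like tracks and
relevé-style seed points accompany each truth polygon. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .curves import PlanarCurve, resample_uniform, write_geojson, write_gpx
from .raster_io import (
    SENTINEL2_BANDS,
    GridTransform,
    MultibandRaster,
    write_raster,
)

REFLECTANCE_SCALE = 10_000  # integer L2A-style reflectance units


def _default_means(level: float) -> dict[str, float]:
    return {b: level for b in SENTINEL2_BANDS}


@dataclass
class HabitatSpec:
    """Spectral/structural description of one synthetic habitat class."""

    code: str
    band_means: dict[str, float]
    band_stds: dict[str, float] = field(default_factory=dict)
    texture: str = "natural"  # natural | plantation
    texture_amp: float = 0.0
    row_period_m: float = 30.0

    def __post_init__(self) -> None:
        if self.texture not in ("natural", "plantation"):
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.texture_amp < 0:
            raise ValueError("texture_amp must be >= 0")
        if any(s < 0 for s in self.band_stds.values()):
            raise ValueError("band_stds must be >= 0")

    def mean(self, band: str) -> float:
        return self.band_means.get(band, 0.0)

    def std(self, band: str) -> float:
        return self.band_stds.get(band, 0.0)


@dataclass
class SceneSpec:
    n_rows: int = 300
    n_cols: int = 300
    pixel_size_m: float = 10.0
    origin: tuple[float, float] = (400_000.0, 5_400_000.0)
    crs_id: str = "EPSG:32634"
    habitats: list[HabitatSpec] = field(default_factory=list)
    background: HabitatSpec | None = None
    n_patches_per_habitat: int = 4
    patch_radius_range_m: tuple[float, float] = (150.0, 250.0)
    noise_std: float = 20.0
    gps_jitter_std_m: float = 5.0
    blend_margin_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_extent_m <= 0:
            raise ValueError("grid must be nonempty")
        if self.background is None:
            self.background = HabitatSpec(
                code="background", band_means=_default_means(1000.0)
            )
        if not self.habitats:
            self.habitats = default_habitats()

    @property
    def row_extent_m(self) -> float:
        return self.n_rows * self.pixel_size_m

    @property
    def transform(self) -> GridTransform:
        return GridTransform(
            self.origin[0], self.origin[1], self.pixel_size_m, self.pixel_size_m
        )


def default_habitats() -> list[HabitatSpec]:
    """Four classes echoing the study design: two mixed-forest types with
    close spectra, a natural conifer stand and a plantation of the same
    species (similar spectra, different texture)."""
    stds = {b: 60.0 for b in SENTINEL2_BANDS}
    mixed_a = {b: 1200.0 for b in SENTINEL2_BANDS}
    mixed_a.update(B03=1500.0, B04=900.0, B08=3600.0, B8A=3500.0, B05=1700.0)
    mixed_b = {b: 1250.0 for b in SENTINEL2_BANDS}
    mixed_b.update(B03=1620.0, B04=980.0, B08=3350.0, B8A=3280.0, B05=1800.0)
    conifer = {b: 900.0 for b in SENTINEL2_BANDS}
    conifer.update(B03=1050.0, B04=700.0, B08=2400.0, B8A=2350.0)
    return [
        HabitatSpec("9130", mixed_a, dict(stds), texture="natural", texture_amp=120.0),
        HabitatSpec("9180", mixed_b, dict(stds), texture="natural", texture_amp=120.0),
        HabitatSpec("9410", dict(conifer), dict(stds), texture="natural",
                    texture_amp=150.0),
        HabitatSpec("planted", dict(conifer), dict(stds), texture="plantation",
                    texture_amp=150.0, row_period_m=30.0),
    ]


def two_class_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Compact two-habitat scene (the two mixed-forest analogues)."""
    habitats = [h for h in default_habitats() if h.code in ("9130", "9180")]
    kw = dict(n_rows=260, n_cols=260, habitats=habitats,
              n_patches_per_habitat=4, patch_radius_range_m=(120.0, 180.0),
              seed=seed)
    kw.update(overrides)
    return SceneSpec(**kw)


# ---------------------------------------------------------------------------

def _blob(center, radius, rng, n_vertices=180, max_perturbation=0.2) -> PlanarCurve:
    """Smooth star-shaped blob: a circle with low-order Fourier radial noise."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 6):
        amp = rng.uniform(0.0, max_perturbation / 4.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = radius * np.clip(r, 1.0 - max_perturbation, 1.0 + max_perturbation)
    x = center[0] + r * np.cos(theta)
    y = center[1] + r * np.sin(theta)
    return PlanarCurve(np.column_stack([x, y]), closed=True)


def _place_patches(spec: SceneSpec, rng) -> list[tuple[HabitatSpec, PlanarCurve]]:
    x0, y0 = spec.origin
    w = spec.n_cols * spec.pixel_size_m
    h = spec.n_rows * spec.pixel_size_m
    placed: list[tuple[HabitatSpec, PlanarCurve, np.ndarray, float]] = []
    r_lo, r_hi = spec.patch_radius_range_m
    for hab in spec.habitats:
        for i in range(spec.n_patches_per_habitat):
            for _attempt in range(500):
                radius = rng.uniform(r_lo, r_hi)
                margin = 1.3 * radius + 2 * spec.pixel_size_m
                if 2 * margin >= min(w, h):
                    continue
                cx = rng.uniform(x0 + margin, x0 + w - margin)
                cy = rng.uniform(y0 - h + margin, y0 - margin)
                c = np.array([cx, cy])
                if all(
                    np.linalg.norm(c - pc) > 1.25 * (radius + pr)
                    for _, _, pc, pr in placed
                ):
                    curve = _blob(c, radius, rng)
                    curve.label = f"{hab.code}-{i}"
                    placed.append((hab, curve, c, radius))
                    break
            else:
                raise RuntimeError(
                    f"could not place patch {i} of habitat {hab.code}; "
                    "reduce radii or patch count"
                )
    return [(hab, curve) for hab, curve, _, _ in placed]


def _texture_field(hab: HabitatSpec, shape, pixel_size, rng):
    if hab.texture_amp == 0:
        return 0.0
    if hab.texture == "natural":
        # dense speckle: heterogeneous crowns of uneven age/height
        speckle = rng.normal(0.0, 1.0, size=shape)
        sm = ndimage.gaussian_filter(speckle, 1.0, mode="reflect")
        sm /= max(sm.std(), 1e-12)
        return hab.texture_amp * sm
    # plantation: an even, smooth canopy with gentle periodic planting rows
    # plus sparse deep gaps (row intersections / skid roads). The gaps carry
    # the region's Laplacian maximum, so only few pixels count as "high".
    rows = np.arange(shape[0])[:, None] * np.ones((1, shape[1]))
    phase = 2 * np.pi * pixel_size / hab.row_period_m
    tex = 0.2 * hab.texture_amp * np.sin(phase * rows)
    n_gaps = max(4, int(shape[0] * shape[1] / 300))
    gr = rng.integers(0, shape[0], n_gaps)
    gc = rng.integers(0, shape[1], n_gaps)
    tex[gr, gc] -= 10.0 * hab.texture_amp
    return tex


def generate_scene(
    spec: SceneSpec,
) -> tuple[MultibandRaster, list[tuple[str, PlanarCurve]]]:
    """Render the scene; returns the raster and (habitat_code, truth) pairs."""
    rng = np.random.default_rng(spec.seed)
    patches = _place_patches(spec, rng)
    shape = (spec.n_rows, spec.n_cols)
    transform = spec.transform
    bg = spec.background

    data = np.empty((len(SENTINEL2_BANDS), *shape), dtype=float)
    for bi, band in enumerate(SENTINEL2_BANDS):
        data[bi] = bg.mean(band) + rng.normal(0.0, bg.std(band) or 0.0, size=shape)
    data += _texture_field(bg, shape, spec.pixel_size_m, rng)

    from .curves import rasterize  # local import avoids cycle at module load

    truths: list[tuple[str, PlanarCurve]] = []
    for hab, curve in patches:
        mask = rasterize(curve, transform, shape=shape).inside
        weight = mask.astype(float)
        if spec.blend_margin_m > 0:
            # ecotone: linear mix of patch and background near the boundary
            dist_in = ndimage.distance_transform_edt(mask) * spec.pixel_size_m
            weight = np.clip(dist_in / spec.blend_margin_m, 0.0, 1.0) * mask
        texture = None
        for bi, band in enumerate(SENTINEL2_BANDS):
            patch_vals = hab.mean(band) + rng.normal(
                0.0, hab.std(band) or 0.0, size=shape
            )
            if texture is None:
                texture = _texture_field(hab, shape, spec.pixel_size_m, rng)
            patch_vals = patch_vals + texture
            data[bi] = np.where(mask, (1 - weight) * data[bi] + weight * patch_vals,
                                data[bi])
        truths.append((hab.code, curve))

    data += rng.normal(0.0, spec.noise_std, size=data.shape)
    data = np.clip(np.rint(data), 0, REFLECTANCE_SCALE * 6).astype(np.uint16)
    raster = MultibandRaster(
        bands=list(SENTINEL2_BANDS),
        data=data,
        transform=transform,
        crs_id=spec.crs_id,
    )
    return raster, truths


def generate_gps_track(
    truth: PlanarCurve,
    jitter_std_m: float = 5.0,
    point_spacing_m: float = 10.0,
    seed: int | None = None,
) -> PlanarCurve:
    """GPS-like track: resampled truth with i.i.d. Gaussian vertex jitter."""
    if not truth.closed:
        raise ValueError("ground-truth curve must be closed")
    rng = np.random.default_rng(seed)
    base = resample_uniform(truth, point_spacing_m)
    jitter = rng.normal(0.0, jitter_std_m, size=base.vertices.shape)
    return PlanarCurve(base.vertices + jitter, closed=True, label=truth.label)


def _centroid_inside(curve: PlanarCurve, rng) -> np.ndarray:
    poly = curve.as_shapely()
    c = np.asarray(poly.centroid.coords[0])
    if poly.contains(shapely_point(c)):
        return c
    # star-shaped blobs essentially always contain their centroid; fall back
    # to rejection sampling inside the bounding box just in case
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(1000):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if poly.contains(shapely_point(p)):
            return p
    raise RuntimeError("could not find interior seed point")


def shapely_point(p):
    import shapely

    return shapely.points(p)


def end_to_end_fixture(spec: SceneSpec, out_dir: str | Path) -> dict:
    """Write raster + truths + GPS tracks + seed points + manifest to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raster, truths = generate_scene(spec)
    rng = np.random.default_rng(spec.seed + 1)

    raster_path = out / "scene.tif"
    write_raster(raster, raster_path)

    truth_curves = [c for _, c in truths]
    truth_path = out / "truths.geojson"
    write_geojson(truth_curves, truth_path)

    tracks = [
        generate_gps_track(c, spec.gps_jitter_std_m, seed=spec.seed + 100 + i)
        for i, (_, c) in enumerate(truths)
    ]
    gpx_path = out / "tracks.gpx"
    write_gpx(tracks, gpx_path, spec.crs_id)

    seeds = []
    for code, curve in truths:
        p = _centroid_inside(curve, rng)
        seeds.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": p.tolist()},
                "properties": {"label": curve.label, "habitat": code},
            }
        )
    seeds_path = out / "seeds.geojson"
    seeds_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": seeds})
    )

    files = {}
    for p in (raster_path, truth_path, gpx_path, seeds_path):
        files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "seed": spec.seed,
        "grid": [spec.n_rows, spec.n_cols, spec.pixel_size_m],
        "origin": list(spec.origin),
        "crs_id": spec.crs_id,
        "habitats": [h.code for h in spec.habitats],
        "n_patches_per_habitat": spec.n_patches_per_habitat,
        "noise_std": spec.noise_std,
        "gps_jitter_std_m": spec.gps_jitter_std_m,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
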