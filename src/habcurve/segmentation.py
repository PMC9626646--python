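"""Evolving-curve segmentation of multiband rasters.

Two modes share one Lagrangian engine:

* automatic: a closed curve grows from a seed under the normal velocity

      V_i = g(|grad I|(x_i)) * delta * H(x_i) - eps * k_i

  where ``g(s) = 1 / (1 + K s^2)`` is the edge detector evaluated on the
  combined multiband gradient magnitude, ``H`` is the binary homogeneity
  indicator (+1 when every driving band's bilinear sample lies inside its
  homogeneity range, -1 otherwise) and ``k_i`` is the discrete curvature
  (positive for locally convex vertices of a counterclockwise ring).

* semiautomatic: open curves between fixed anchor points relax under

      V_i = -eta * (grad g . N_i) - eps * k_i

  i.e. steepest descent toward the valley of the edge-detector potential,
  smoothed by curvature.

Both use explicit Euler steps followed by uniform arclength redistribution
of the vertices; the engine is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curves import CurveError, PlanarCurve, clean_ring, rasterize, resample_uniform
from .raster_io import (
    MultibandRaster,
    ScalarField,
    gaussian_smooth,
    gradient,
    sample_bilinear,
)

DEFAULT_DRIVING_BANDS = ("B02", "B03", "B04", "B08")

#: presets for the homogeneity-range width knob: monodominant stands are
#: spectrally tight and need a narrower range than mixed forests.
K_SIGMA_PRESETS = {"monodominant": 1.5, "mixed": 2.5}


class StabilityError(ValueError):
    pass


class CollapseError(RuntimeError):
    """Curve shrank below 3 usable vertices during evolution."""


@dataclass
class SegmentationParams:
    """All evolution-model constants. Stability contract: dt*eps/h^2 <= 0.25."""

    driving_bands: tuple[str, ...] = DEFAULT_DRIVING_BANDS
    sigma_px: float = 1.0
    homogeneity_lo: dict[str, float] = field(default_factory=dict)
    homogeneity_hi: dict[str, float] = field(default_factory=dict)
    expansion_weight: float = 2.0        # delta
    edge_sensitivity: float = 1.0        # K in g(s) = 1/(1 + K s^2)
    curvature_weight: float = 5.0        # eps
    edge_attraction: float = 200.0       # eta (semiautomatic mode)
    time_step: float = 1.0               # dt
    vertex_spacing: float = 10.0         # h, meters
    max_iters: int = 500
    convergence_tol: float = 0.05        # max vertex displacement (m), 10-step avg

    def __post_init__(self) -> None:
        for name in ("expansion_weight", "edge_sensitivity", "curvature_weight",
                     "edge_attraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        if self.time_step <= 0 or self.vertex_spacing <= 0:
            raise ValueError("time_step and vertex_spacing must be positive")
        for b in self.homogeneity_lo:
            if b in self.homogeneity_hi and (
                self.homogeneity_lo[b] > self.homogeneity_hi[b]
            ):
                raise ValueError(f"homogeneity_lo > homogeneity_hi for band {b}")
        cfl = self.time_step * self.curvature_weight / self.vertex_spacing**2
        if cfl > 0.25 + 1e-12:
            raise StabilityError(
                f"dt*eps/h^2 = {cfl:.3f} violates the <= 0.25 stability contract"
            )


@dataclass
class SeedSpec:
    """Segmentation starting region: a point, a circle or a polygon."""

    kind: str = "circle"  # point | circle | polygon
    center: tuple[float, float] | None = None
    radius_m: float = 30.0
    polygon: PlanarCurve | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "circle", "polygon"):
            raise ValueError(f"unknown seed kind {self.kind!r}")
        if self.kind == "polygon":
            if self.polygon is None or not self.polygon.closed:
                raise ValueError("polygon seed requires a closed PlanarCurve")
        else:
            if self.center is None:
                raise ValueError(f"{self.kind} seed requires a center")
            if self.radius_m <= 0:
                raise ValueError("radius_m must be positive")

    def initial_curve(self, vertex_spacing: float) -> PlanarCurve:
        if self.kind == "polygon":
            return resample_uniform(self.polygon, vertex_spacing)
        n = max(16, int(round(2 * np.pi * self.radius_m / vertex_spacing)))
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        cx, cy = self.center
        ring = np.column_stack(
            [cx + self.radius_m * np.cos(theta), cy + self.radius_m * np.sin(theta)]
        )
        return PlanarCurve(ring, closed=True)


@dataclass
class SegmentationFields:
    """Image quantities precomputed once per (raster, params) pair."""

    smoothed: dict[str, ScalarField]
    edge_g: ScalarField
    edge_g_dx: ScalarField
    edge_g_dy: ScalarField


@dataclass
class Diagnostics:
    iterations: int = 0
    final_mean_displacement: float = float("nan")
    converged: bool = False
    clamped: bool = False
    displacement_log: list[float] = field(default_factory=list)


def homogeneity_from_seed(
    raster: MultibandRaster,
    seed: SeedSpec,
    params: SegmentationParams,
    k_sigma: float = 2.0,
) -> SegmentationParams:
    """Estimate per-band homogeneity ranges as seed mean -/+ k_sigma * std."""
    region = rasterize(seed.initial_curve(params.vertex_spacing), raster)
    mask = region.inside & raster.valid_mask()
    if mask.sum() < 4:
        raise ValueError(
            f"seed region has {int(mask.sum())} valid pixels, need >= 4"
        )
    lo = dict(params.homogeneity_lo)
    hi = dict(params.homogeneity_hi)
    for b in params.driving_bands:
        vals = raster.band(b)[mask].astype(float)
        mu, sd = float(vals.mean()), float(vals.std())
        lo[b] = mu - k_sigma * sd
        hi[b] = mu + k_sigma * sd
    return replace(params, homogeneity_lo=lo, homogeneity_hi=hi)


def prepare_fields(
    raster: MultibandRaster,
    params: SegmentationParams,
    band_scales: dict[str, float] | None = None,
) -> SegmentationFields:
    """Smooth driving bands and build the edge-detector potential g.

    The scalar edge strength is the Euclidean norm across driving bands of
    the per-band smoothed gradients, each normalized by ``band_scales``
    (typically the seed-region std) so the edge sensitivity K is scale-free.
    """
    smoothed: dict[str, ScalarField] = {}
    sq_sum = None
    for b in params.driving_bands:
        f = raster.scalar_field(b)
        sf = gaussian_smooth(f, params.sigma_px) if params.sigma_px > 0 else f
        smoothed[b] = sf
        gx, gy = gradient(sf)
        scale = 1.0
        if band_scales:
            scale = max(band_scales.get(b, 1.0), 1e-12)
        mag2 = (gx.data**2 + gy.data**2) / scale**2
        sq_sum = mag2 if sq_sum is None else sq_sum + mag2
    g = 1.0 / (1.0 + params.edge_sensitivity * sq_sum)
    edge_g = ScalarField(g, raster.transform, "edge-detector g")
    g_dx, g_dy = gradient(edge_g)
    return SegmentationFields(smoothed, edge_g, g_dx, g_dy)


def seed_band_scales(
    raster: MultibandRaster, seed: SeedSpec, params: SegmentationParams
) -> dict[str, float]:
    """Per-band normalization for the edge field: seed-region std, falling
    back to the global band std when the seed is spectrally flat."""
    region = rasterize(seed.initial_curve(params.vertex_spacing), raster)
    mask = region.inside & raster.valid_mask()
    scales = {}
    for b in params.driving_bands:
        band = raster.band(b).astype(float)
        sd = float(band[mask].std()) if mask.any() else 0.0
        if sd <= 0:
            sd = float(band.std())
        scales[b] = sd if sd > 0 else 1.0
    return scales


# ---------------------------------------------------------------------------
# engine internals

def _extent(raster: MultibandRaster) -> tuple[float, float, float, float]:
    t = raster.transform
    nrows, ncols = raster.shape
    return (
        t.origin_x,
        t.origin_x + ncols * t.pixel_size_x,
        t.origin_y - nrows * t.pixel_size_y,
        t.origin_y,
    )


def _clamp_to_extent(v: np.ndarray, extent, margin: float) -> tuple[np.ndarray, bool]:
    x0, x1, y0, y1 = extent
    out = v.copy()
    out[:, 0] = np.clip(out[:, 0], x0 + margin, x1 - margin)
    out[:, 1] = np.clip(out[:, 1], y0 + margin, y1 - margin)
    return out, bool(np.any(out != v))


def _normals_and_curvature(v: np.ndarray, closed: bool):
    """Outward unit normals and signed curvature for a CCW vertex chain.

    Curvature is the normal projection of the arclength second difference,
    so a CCW circle of radius r yields k ~ +1/r at every vertex.
    """
    if closed:
        prev_v = np.roll(v, 1, axis=0)
        next_v = np.roll(v, -1, axis=0)
    else:
        prev_v = np.vstack([v[0], v[:-1]])
        next_v = np.vstack([v[1:], v[-1]])
    fwd = next_v - v
    bwd = v - prev_v
    tangent = next_v - prev_v
    t_norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    t_norm[t_norm == 0] = 1.0
    tangent = tangent / t_norm
    # CCW ring: rotating the tangent by -90 deg points outward
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    h = 0.5 * (np.linalg.norm(fwd, axis=1) + np.linalg.norm(bwd, axis=1))
    h[h == 0] = 1.0
    second = next_v - 2.0 * v + prev_v
    curvature = -np.einsum("ij,ij->i", second, normal) / h**2
    if not closed:
        curvature[[0, -1]] = 0.0
    return normal, curvature


def _homogeneity_sign(
    pts: np.ndarray, fields: SegmentationFields, params: SegmentationParams
) -> np.ndarray:
    ok = np.ones(len(pts), dtype=bool)
    for b in params.driving_bands:
        vals = sample_bilinear(fields.smoothed[b], pts)
        ok &= (vals >= params.homogeneity_lo[b]) & (vals <= params.homogeneity_hi[b])
    return np.where(ok, 1.0, -1.0)


def evolve_step(
    curve: PlanarCurve,
    fields: SegmentationFields,
    params: SegmentationParams,
    raster: MultibandRaster,
) -> tuple[PlanarCurve, float, bool]:
    """One explicit Euler step of the closed-curve model.

    Returns (new curve, mean vertex displacement in m, clamped?).
    """
    if not curve.closed or len(curve) < 3:
        raise CurveError("evolve_step requires a closed curve with >= 3 vertices")
    v = curve.vertices
    normal, curvature = _normals_and_curvature(v, closed=True)
    g = sample_bilinear(fields.edge_g, v)
    h_sign = _homogeneity_sign(v, fields, params)
    speed = (
        g * params.expansion_weight * h_sign
        - params.curvature_weight * curvature
    )
    moved = v + params.time_step * speed[:, None] * normal
    extent = _extent(raster)
    margin = 0.51 * max(
        raster.transform.pixel_size_x, raster.transform.pixel_size_y
    )
    moved, clamped = _clamp_to_extent(moved, extent, margin)
    displacement = float(np.max(np.linalg.norm(moved - v, axis=1)))
    try:
        new_curve = resample_uniform(
            PlanarCurve(moved, closed=True, label=curve.label),
            params.vertex_spacing,
        )
    except CurveError as exc:
        raise CollapseError(f"curve collapsed during evolution: {exc}") from exc
    return new_curve, displacement, clamped


def automatic_segment(
    raster: MultibandRaster,
    seed: SeedSpec,
    params: SegmentationParams,
    band_scales: dict[str, float] | None = None,
) -> tuple[PlanarCurve, Diagnostics]:
    """Grow a closed curve from a seed until the displacement tolerance.

    The homogeneity ranges must already be populated for every driving band
    (use :func:`homogeneity_from_seed`). Non-convergence at ``max_iters``
    returns the best curve with ``converged=False``. ``band_scales`` defaults
    to the seed-region std per band, making the edge sensitivity scale-free.
    """
    missing = [b for b in params.driving_bands if b not in params.homogeneity_lo]
    if missing:
        raise ValueError(f"homogeneity range missing for bands {missing}")
    if band_scales is None:
        band_scales = seed_band_scales(raster, seed, params)
    fields = prepare_fields(raster, params, band_scales=band_scales)
    curve = seed.initial_curve(params.vertex_spacing)
    diag = Diagnostics()
    window: list[float] = []
    for it in range(1, params.max_iters + 1):
        curve, disp, clamped = evolve_step(curve, fields, params, raster)
        diag.clamped |= clamped
        diag.displacement_log.append(disp)
        if it % 25 == 0:
            curve = clean_ring(curve.vertices, label=curve.label)
            curve = resample_uniform(curve, params.vertex_spacing)
        window.append(disp)
        if len(window) > 10:
            window.pop(0)
        diag.iterations = it
        diag.final_mean_displacement = float(np.mean(window))
        if len(window) == 10 and diag.final_mean_displacement < params.convergence_tol:
            diag.converged = True
            break
    curve = clean_ring(curve.vertices, label=curve.label)
    return curve, diag


def semiautomatic_segment(
    raster: MultibandRaster,
    anchors: Sequence[tuple[float, float]],
    params: SegmentationParams,
    band_scales: dict[str, float] | None = None,
) -> tuple[PlanarCurve, Diagnostics]:
    """Fit open curves between consecutive anchors to the nearest image edge.

    Each anchor pair starts as a straight segment; interior vertices relax
    along their normals toward the valley of the edge-detector potential
    while endpoints stay fixed. If the last anchor coincides with the first,
    the concatenation is returned closed.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 2)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    for a, b in zip(anchors[:-1], anchors[1:]):
        if np.linalg.norm(a - b) < 1e-9:
            raise ValueError("coincident consecutive anchors")
    extent = _extent(raster)
    x0, x1, y0, y1 = extent
    if np.any(anchors[:, 0] < x0) or np.any(anchors[:, 0] > x1) or \
       np.any(anchors[:, 1] < y0) or np.any(anchors[:, 1] > y1):
        raise ValueError("anchor outside raster extent")

    if band_scales is None:
        band_scales = {
            b: float(raster.band(b).astype(float).std()) or 1.0
            for b in params.driving_bands
        }
    fields = prepare_fields(raster, params, band_scales=band_scales)

    diag = Diagnostics()
    pieces: list[np.ndarray] = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        piece, it, disp, conv = _evolve_open_segment(a, b, fields, params, extent)
        diag.iterations = max(diag.iterations, it)
        diag.final_mean_displacement = disp
        diag.converged = conv
        pieces.append(piece[:-1])
    vertices = np.vstack(pieces + [anchors[-1][None]])
    closed = bool(np.linalg.norm(anchors[0] - anchors[-1]) < 1e-9)
    if closed:
        curve = PlanarCurve(vertices[:-1], closed=True)
    else:
        curve = PlanarCurve(vertices, closed=False)
    return curve, diag


def _evolve_open_segment(a, b, fields, params, extent, v0=None):
    if v0 is not None:
        v = np.asarray(v0, dtype=float).copy()
    else:
        length = float(np.linalg.norm(b - a))
        n_seg = max(1, int(round(length / params.vertex_spacing)))
        t = np.linspace(0.0, 1.0, n_seg + 1)
        v = a[None] + t[:, None] * (b - a)[None]
    margin = 0.51 * fields.edge_g.transform.pixel_size_x
    window: list[float] = []
    converged = False
    disp = 0.0
    for it in range(1, params.max_iters + 1):
        if len(v) > 2:
            normal, curvature = _normals_and_curvature(v, closed=False)
            gdx = sample_bilinear(fields.edge_g_dx, v)
            gdy = sample_bilinear(fields.edge_g_dy, v)
            grad_g_n = gdx * normal[:, 0] + gdy * normal[:, 1]
            speed = -params.edge_attraction * grad_g_n - params.curvature_weight * curvature
            speed[[0, -1]] = 0.0
            moved = v + params.time_step * speed[:, None] * normal
            moved, _ = _clamp_to_extent(moved, extent, margin)
            moved[0], moved[-1] = a, b
            disp = float(np.max(np.linalg.norm(moved - v, axis=1)))
            piece = resample_uniform(
                PlanarCurve(moved, closed=False), params.vertex_spacing
            )
            v = piece.vertices
            v[0], v[-1] = a, b
        else:
            disp = 0.0
        window.append(disp)
        if len(window) > 10:
            window.pop(0)
        if np.mean(window) < params.convergence_tol and (len(window) == 10 or len(v) <= 2):
            converged = True
            break
    return v, it, float(np.mean(window)), converged
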