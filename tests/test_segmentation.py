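import math

import numpy as np
import pytest

from habcurve import (
    PlanarCurve,
    SeedSpec,
    SegmentationParams,
    automatic_segment,
    evolve_step,
    homogeneity_from_seed,
    hausdorff_mean,
    polygon_area_ha,
    prepare_fields,
    semiautomatic_segment,
)
from habcurve.segmentation import StabilityError, _extent, _evolve_open_segment

from conftest import circle_curve, disk_raster, make_raster


def flat_raster(value=100.0, n=64, band="B04"):
    from habcurve.raster_io import GridTransform

    t = GridTransform(0.0, 0.0, 10.0, 10.0)
    return make_raster(np.full((n, n), value), t, bands=[band])


def b04_params(**kw):
    defaults = dict(
        driving_bands=("B04",),
        homogeneity_lo={"B04": -1e12},
        homogeneity_hi={"B04": 1e12},
        expansion_weight=2.0,
        curvature_weight=0.0,
        time_step=1.0,
        vertex_spacing=10.0,
    )
    defaults.update(kw)
    return SegmentationParams(**defaults)


class TestParams:
    def test_stability_contract_enforced(self):
        with pytest.raises(StabilityError):
            SegmentationParams(time_step=1.0, curvature_weight=50.0,
                               vertex_spacing=10.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(expansion_weight=-1.0)

    def test_inverted_homogeneity_range(self):
        with pytest.raises(ValueError):
            SegmentationParams(
                homogeneity_lo={"B04": 10.0}, homogeneity_hi={"B04": 5.0}
            )


class TestHomogeneityFromSeed:
    def test_constant_band(self):
        r = flat_raster(100.0)
        seed = SeedSpec(kind="circle", center=(320.0, -320.0), radius_m=30.0)
        p = homogeneity_from_seed(r, seed, b04_params(), k_sigma=2.0)
        assert p.homogeneity_lo["B04"] == pytest.approx(100.0)
        assert p.homogeneity_hi["B04"] == pytest.approx(100.0)

    def test_four_pixel_oracle(self):
        # seed covering exactly pixels {90, 100, 110, 100}:
        # mean 100, population std sqrt(50) = 7.0710678...
        r = flat_raster(100.0, n=8)
        r.data[0, 3, 3] = 90.0
        r.data[0, 3, 4] = 100.0
        r.data[0, 4, 3] = 110.0
        r.data[0, 4, 4] = 100.0
        # circle radius 10 m centered on the shared corner of those 4 pixels
        seed = SeedSpec(kind="circle", center=(40.0, -40.0), radius_m=10.0)
        p = homogeneity_from_seed(r, seed, b04_params(), k_sigma=2.0)
        assert p.homogeneity_lo["B04"] == pytest.approx(85.85786437626905)
        assert p.homogeneity_hi["B04"] == pytest.approx(114.14213562373095)

    def test_zero_k_sigma(self):
        r = flat_raster(100.0, n=8)
        r.data[0, 3, 3] = 90.0
        seed = SeedSpec(kind="circle", center=(40.0, -40.0), radius_m=10.0)
        p = homogeneity_from_seed(r, seed, b04_params(), k_sigma=0.0)
        assert p.homogeneity_lo["B04"] == p.homogeneity_hi["B04"]
        assert p.homogeneity_lo["B04"] == pytest.approx(97.5)

    def test_seed_outside_raster(self):
        r = flat_raster(100.0, n=8)
        seed = SeedSpec(kind="circle", center=(5000.0, -5000.0), radius_m=10.0)
        with pytest.raises(ValueError):
            homogeneity_from_seed(r, seed, b04_params())


class TestEvolveStep:
    def test_uniform_outward_on_in_range_image(self):
        r = flat_raster(100.0)
        p = b04_params(homogeneity_lo={"B04": 0.0}, homogeneity_hi={"B04": 200.0})
        fields = prepare_fields(r, p)
        c = circle_curve(320.0, -320.0, 100.0, n=63)
        new, disp, clamped = evolve_step(c, fields, p, r)
        # g=1 (flat image), H=+1, eps=0 -> every vertex moves out by dt*delta
        assert disp == pytest.approx(2.0, abs=1e-9)
        radii = np.linalg.norm(new.vertices - [320.0, -320.0], axis=1)
        sagitta = 102.0 * (1 - np.cos(np.pi / 63))  # chord resampling slack
        assert np.all(radii <= 102.0 + 1e-9)
        assert np.all(radii >= 102.0 - sagitta - 1e-9)
        assert not clamped

    def test_uniform_inward_on_out_of_range_image(self):
        r = flat_raster(500.0)
        p = b04_params(homogeneity_lo={"B04": 0.0}, homogeneity_hi={"B04": 200.0})
        fields = prepare_fields(r, p)
        c = circle_curve(320.0, -320.0, 100.0, n=63)
        new, disp, _ = evolve_step(c, fields, p, r)
        assert disp == pytest.approx(2.0, abs=1e-9)
        radii = np.linalg.norm(new.vertices - [320.0, -320.0], axis=1)
        assert np.allclose(radii, 100.0 - 2.0, atol=0.15)

    def test_curve_shortening_matches_closed_form(self):
        # delta=0, eps>0: circle radius obeys r(t) = sqrt(r0^2 - 2*eps*t)
        r = flat_raster(100.0)
        eps, dt, steps, r0 = 5.0, 1.0, 50, 100.0
        p = b04_params(expansion_weight=0.0, curvature_weight=eps, time_step=dt)
        fields = prepare_fields(r, p)
        c = circle_curve(320.0, -320.0, r0, n=63)
        for _ in range(steps):
            c, _, _ = evolve_step(c, fields, p, r)
        radii = np.linalg.norm(c.vertices - [320.0, -320.0], axis=1)
        expected = math.sqrt(r0**2 - 2 * eps * dt * steps)
        assert abs(radii.mean() - expected) / expected < 0.01

    def test_displacement_bounded(self):
        # |V| <= g*delta + eps*|k| with g <= 1; on smooth random scenes the
        # per-step displacement stays under dt*(delta + eps/h)
        rng = np.random.default_rng(12)
        r = flat_raster(100.0)
        r.data[0] += rng.normal(0, 10, r.data[0].shape)
        p = b04_params(homogeneity_lo={"B04": 0.0}, homogeneity_hi={"B04": 200.0},
                       curvature_weight=5.0, time_step=1.0)
        fields = prepare_fields(r, p, band_scales={"B04": 10.0})
        c = circle_curve(320.0, -320.0, 80.0, n=51)
        bound = p.time_step * (p.expansion_weight + p.curvature_weight / p.vertex_spacing)
        for _ in range(20):
            old = c.vertices.copy()
            c, disp, _ = evolve_step(c, fields, p, r)
            assert disp <= bound + 1e-9


class TestAutomatic:
    def test_disk_recovery(self):
        raster, (xc, yc) = disk_raster(noise_seed=0)
        seed = SeedSpec(kind="circle", center=(xc, yc), radius_m=30.0)
        p = SegmentationParams(
            driving_bands=("B04",), expansion_weight=2.0, curvature_weight=2.0,
            time_step=0.5, vertex_spacing=10.0, max_iters=800, convergence_tol=0.2,
        )
        p = homogeneity_from_seed(raster, seed, p, k_sigma=4.0)
        curve, diag = automatic_segment(raster, seed, p)
        truth = circle_curve(xc, yc, 200.0, n=720)
        assert hausdorff_mean(curve, truth) < 10.0
        area = polygon_area_ha(curve) * 10_000
        assert abs(area - math.pi * 200**2) / (math.pi * 200**2) < 0.05

    def test_unbounded_growth_flags_nonconvergence(self):
        r = flat_raster(100.0)
        p = b04_params(homogeneity_lo={"B04": 0.0}, homogeneity_hi={"B04": 200.0},
                       max_iters=30, convergence_tol=0.01)
        seed = SeedSpec(kind="circle", center=(320.0, -320.0), radius_m=30.0)
        curve, diag = automatic_segment(r, seed, p)
        assert diag.iterations == 30
        assert not diag.converged

    def test_pure_curvature_flow_shrinks_area(self):
        r = flat_raster(100.0)
        p = b04_params(expansion_weight=0.0, curvature_weight=5.0)
        fields = prepare_fields(r, p)
        c = circle_curve(320.0, -320.0, 120.0, n=75)
        areas = [polygon_area_ha(c)]
        for _ in range(30):
            c, _, _ = evolve_step(c, fields, p, r)
            areas.append(polygon_area_ha(c))
        assert all(a2 < a1 for a1, a2 in zip(areas, areas[1:]))

    def test_monotone_outward_growth_noise_free(self):
        raster, (xc, yc) = disk_raster(noise_seed=0, noise_std=0.0)
        p = SegmentationParams(
            driving_bands=("B04",), homogeneity_lo={"B04": 110.0},
            homogeneity_hi={"B04": 130.0}, expansion_weight=2.0,
            curvature_weight=0.0, time_step=0.5, vertex_spacing=10.0,
        )
        fields = prepare_fields(raster, p, band_scales={"B04": 30.0})
        c = circle_curve(xc, yc, 30.0, n=19)
        areas = [polygon_area_ha(c)]
        max_radius = [30.0]
        for _ in range(250):
            c, _, _ = evolve_step(c, fields, p, raster)
            areas.append(polygon_area_ha(c))
            max_radius.append(np.linalg.norm(c.vertices - [xc, yc], axis=1).max())
        hit = next(i for i, r in enumerate(max_radius) if r >= 190.0)
        grow = np.diff(areas)[:hit]
        assert np.all(grow > -1e-9)

    def test_determinism(self):
        raster, (xc, yc) = disk_raster(noise_seed=3)
        seed = SeedSpec(kind="circle", center=(xc, yc), radius_m=30.0)
        p = SegmentationParams(driving_bands=("B04",), time_step=0.5,
                               curvature_weight=2.0, max_iters=150)
        p = homogeneity_from_seed(raster, seed, p, k_sigma=4.0)
        c1, d1 = automatic_segment(raster, seed, p)
        c2, d2 = automatic_segment(raster, seed, p)
        assert np.array_equal(c1.vertices, c2.vertices)
        assert d1.iterations == d2.iterations

    def test_missing_homogeneity_range(self):
        r = flat_raster(100.0)
        seed = SeedSpec(kind="circle", center=(320.0, -320.0), radius_m=30.0)
        with pytest.raises(ValueError, match="homogeneity"):
            automatic_segment(r, seed, SegmentationParams(driving_bands=("B04",)))


class TestSemiautomatic:
    def test_flat_image_keeps_straight_line(self):
        r = flat_raster(100.0, n=100)
        p = b04_params(curvature_weight=5.0, time_step=0.5, max_iters=50,
                       convergence_tol=0.01)
        anchors = [(100.0, -100.0), (800.0, -700.0)]
        curve, diag = semiautomatic_segment(r, anchors, p)
        # every vertex on the straight chord between the anchors
        a, b = np.array(anchors[0]), np.array(anchors[1])
        d = b - a
        rel = curve.vertices - a
        cross = np.abs(d[0] * rel[:, 1] - d[1] * rel[:, 0]) / np.linalg.norm(d)
        assert cross.max() < 1e-9
        assert diag.converged

    def test_step_edge_lock_on(self):
        # vertical reflectance step at x=500; perturbed initial line must
        # return to within half a pixel of the edge
        n = 100
        r = flat_raster(60.0, n=n)
        x = (np.arange(n) + 0.5) * 10.0
        r.data[0][:, x >= 500.0] = 120.0
        p = SegmentationParams(
            driving_bands=("B04",), sigma_px=3.0, curvature_weight=5.0,
            edge_attraction=3000.0, time_step=0.5, vertex_spacing=10.0,
            max_iters=3000, convergence_tol=0.005,
        )
        fields = prepare_fields(r, p, band_scales={"B04": float(r.data[0].std())})
        a, b = np.array([500.0, -10.0]), np.array([500.0, -990.0])
        t = np.linspace(0.0, 1.0, 99)
        v0 = a[None] + t[:, None] * (b - a)[None]
        v0[1:-1, 0] += 30.0
        v, _, _, conv = _evolve_open_segment(a, b, fields, p, _extent(r), v0=v0)
        assert conv
        assert np.abs(v[2:-2, 0] - 500.0).max() < 5.0

    def test_two_close_anchors_trivial(self):
        r = flat_raster(100.0)
        p = b04_params(convergence_tol=0.01)
        curve, diag = semiautomatic_segment(r, [(100.0, -100.0), (110.0, -100.0)], p)
        assert len(curve) == 2
        assert diag.converged
        assert diag.iterations <= 2

    def test_closed_when_last_anchor_repeats_first(self):
        r = flat_raster(100.0)
        p = b04_params(curvature_weight=2.0, time_step=0.5, max_iters=30)
        anchors = [(200.0, -200.0), (400.0, -200.0), (400.0, -400.0),
                   (200.0, -400.0), (200.0, -200.0)]
        curve, _ = semiautomatic_segment(r, anchors, p)
        assert curve.closed

    def test_anchor_outside_raster(self):
        r = flat_raster(100.0)
        with pytest.raises(ValueError, match="outside"):
            semiautomatic_segment(r, [(100.0, -100.0), (9999.0, -100.0)], b04_params())

    def test_coincident_anchors(self):
        r = flat_raster(100.0)
        with pytest.raises(ValueError, match="coincident"):
            semiautomatic_segment(r, [(100.0, -100.0), (100.0, -100.0)], b04_params())
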