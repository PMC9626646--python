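import numpy as np
import pytest

from habcurve import GridTransform, MultibandRaster, PlanarCurve, SENTINEL2_BANDS


@pytest.fixture
def transform10():
    """10 m north-up grid with origin at (0, 0); world y runs negative."""
    return GridTransform(0.0, 0.0, 10.0, 10.0)


@pytest.fixture
def utm_transform():
    return GridTransform(400_000.0, 5_400_000.0, 10.0, 10.0)


def make_raster(data, transform, bands=None, **kw):
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if bands is None:
        bands = [f"B{i:02d}" for i in range(2, 2 + data.shape[0])]
    return MultibandRaster(list(bands), data, transform, **kw)


@pytest.fixture
def raster14(transform10):
    """Deterministic 32x32 raster with the canonical 14 bands."""
    rng = np.random.default_rng(7)
    data = (rng.random((14, 32, 32)) * 3000).astype(np.uint16)
    return MultibandRaster(list(SENTINEL2_BANDS), data, transform10)


def circle_curve(cx, cy, radius, n=256, label=""):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return PlanarCurve(
        np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)]),
        closed=True,
        label=label,
    )


def disk_raster(noise_seed=0, noise_std=6.0, n=64, inside=120.0, outside=60.0,
                radius=200.0, band="B04"):
    """Single-band scene: a disk of ``inside`` value on ``outside`` background."""
    t = GridTransform(0.0, 0.0, 10.0, 10.0)
    rng = np.random.default_rng(noise_seed)
    cols, rows = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5)
    x, y = cols * 10.0, -rows * 10.0
    xc, yc = n * 5.0, -n * 5.0
    rr = np.hypot(x - xc, y - yc)
    img = np.where(rr <= radius, inside, outside) + rng.normal(0, noise_std, (n, n))
    return MultibandRaster([band], img[None], t), (xc, yc)
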