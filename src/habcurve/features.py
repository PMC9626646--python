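"""Per-segment spectral signatures and the Relative High Laplacian classifier.

A segment on a 14-band raster is characterized by 56 values: mean, min, max
and population standard deviation per band. RHL N% measures canopy
structural heterogeneity: the fraction of region pixels whose absolute
smoothed-Laplacian response exceeds N% of the region maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import RegionMask
from .raster_io import MultibandRaster, gaussian_smooth, laplacian

STAT_NAMES = ("mean", "min", "max", "std")


@dataclass
class SpectralSummary:
    """Per-band {mean, min, max, std} statistics of a segment."""

    segment_label: str
    date_tag: str
    stats: dict[str, dict[str, float]]  # band -> stat -> value
    n_pixels: int

    def flatten(self) -> dict[str, float]:
        """Flat ``{band}_{stat}`` mapping; 14 bands x 4 stats = 56 values."""
        return {
            f"{band}_{stat}": self.stats[band][stat]
            for band in self.stats
            for stat in STAT_NAMES
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "segment": self.segment_label,
                "date": self.date_tag,
                "band": band,
                "stat": stat,
                "value": self.stats[band][stat],
            }
            for band in self.stats
            for stat in STAT_NAMES
        ]
        return pd.DataFrame(rows)


@dataclass
class RHLResult:
    segment_label: str
    band: str
    threshold_pct: float
    max_abs_laplacian: float
    high_pixel_count: int
    total_pixel_count: int

    @property
    def rhl(self) -> float:
        return self.high_pixel_count / self.total_pixel_count


def spectral_characteristics(
    raster: MultibandRaster,
    region: RegionMask,
    label: str = "",
    date_tag: str = "",
) -> SpectralSummary:
    """Zonal statistics over valid in-region pixels; std is population std."""
    per_band: dict[str, dict[str, float]] = {}
    n_pixels = 0
    for band in raster.bands:
        mask = region.inside & raster.valid_mask(band)
        if not mask.any():
            raise ValueError(
                f"region empty (or entirely nodata) for band {band}"
            )
        vals = raster.band(band)[mask].astype(float)
        n_pixels = int(mask.sum())
        per_band[band] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "std": float(vals.std()),  # population
        }
    return SpectralSummary(label, date_tag, per_band, n_pixels)


def rhl(
    raster: MultibandRaster,
    region: RegionMask,
    band: str,
    threshold_pct: float = 10.0,
    sigma_px: float = 1.0,
    label: str = "",
) -> RHLResult:
    """Relative High Laplacian ratio for one band over one region.

    Pipeline: Gaussian smooth (skipped when ``sigma_px`` == 0) -> 5-point
    Laplacian -> restrict |response| to the region -> threshold at
    ``threshold_pct`` percent of the region maximum. A perfectly flat region
    (MAX = 0) yields rhl = 0 by convention.
    """
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError(f"threshold_pct must be in (0, 100), got {threshold_pct}")
    mask = region.inside & raster.valid_mask(band)
    total = int(mask.sum())
    if total < 9:
        raise ValueError(f"region too small for RHL ({total} px, need >= 9)")
    f = raster.scalar_field(band)
    if sigma_px > 0:
        f = gaussian_smooth(f, sigma_px)
    lap = np.abs(laplacian(f).data)
    region_lap = lap[mask]
    max_abs = float(region_lap.max())
    high = int((region_lap > (threshold_pct / 100.0) * max_abs).sum()) if max_abs > 0 else 0
    return RHLResult(
        segment_label=label,
        band=band,
        threshold_pct=threshold_pct,
        max_abs_laplacian=max_abs,
        high_pixel_count=high,
        total_pixel_count=total,
    )


def rhl_contrast(
    raster: MultibandRaster,
    regions_a: list[RegionMask],
    regions_b: list[RegionMask],
    band: str = "B04",
    threshold_pct: float = 10.0,
    sigma_px: float = 1.0,
):
    """Welch two-sample t test on per-region RHL values of two groups.

    Returns (rhl values a, rhl values b, mean_a, mean_b, t, p).
    """
    if len(regions_a) < 2 or len(regions_b) < 2:
        raise ValueError("each group needs >= 2 regions")
    va = np.array([rhl(raster, r, band, threshold_pct, sigma_px).rhl for r in regions_a])
    vb = np.array([rhl(raster, r, band, threshold_pct, sigma_px).rhl for r in regions_b])
    if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(va, vb, equal_var=False)
    return va, vb, float(va.mean()), float(vb.mean()), float(t_stat), float(p_val)
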