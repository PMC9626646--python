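"""habcurve: evolving-curve habitat segmentation for multiband rasters.

Segment vegetation habitats on Sentinel-2-style imagery by Lagrangian curve
evolution, characterize segments spectrally and structurally, validate
boundaries against GPS tracks with Hausdorff distances, and test habitat
differentiation with PERMANOVA.
"""

from importlib import resources as _resources

from .raster_io import (  # noqa: F401
    SENTINEL2_BANDS,
    GridTransform,
    MultibandRaster,
    ScalarField,
    gaussian_smooth,
    gradient,
    laplacian,
    read_raster,
    sample_bilinear,
    write_raster,
)
from .curves import (  # noqa: F401
    PlanarCurve,
    RegionMask,
    polygon_area_ha,
    rasterize,
    read_geojson,
    read_gpx,
    resample_uniform,
    write_geojson,
    write_gpx,
)
from .segmentation import (  # noqa: F401
    SeedSpec,
    SegmentationParams,
    automatic_segment,
    evolve_step,
    homogeneity_from_seed,
    prepare_fields,
    semiautomatic_segment,
)
from .features import (  # noqa: F401
    RHLResult,
    SpectralSummary,
    rhl,
    rhl_contrast,
    spectral_characteristics,
)
from .evaluation import (  # noqa: F401
    DistanceReport,
    DistanceRow,
    FeatureMatrix,
    band_combination_screen,
    build_distance_report,
    hausdorff_max,
    hausdorff_mean,
    load_distance_table,
    permanova,
)
from .synthetic_scene import (  # noqa: F401
    HabitatSpec,
    SceneSpec,
    end_to_end_fixture,
    generate_gps_track,
    generate_scene,
)

__version__ = "0.1.0"


def packaged_distance_table(which: str):
    """Load one of the shipped per-segment Hausdorff tables
    (``"semiauto"`` or ``"auto"``) as an aggregated DistanceReport."""
    name = {"semiauto": "hausdorff_semiauto.csv", "auto": "hausdorff_auto.csv"}[which]
    ref = _resources.files("habcurve.data").joinpath(name)
    with _resources.as_file(ref) as path:
        return load_distance_table(path)
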