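"""Curve-accuracy metrics, distance reports and multivariate habitat tests.

Hausdorff distances are computed on densified polylines with exact
point-to-segment geometry (shapely), so accuracy is governed only by the
densification step. The PERMANOVA is a from-scratch implementation of the
distance-based one-way sums-of-squares partition with label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist, squareform

from .curves import PlanarCurve, densify

DEFAULT_DENSIFY_M = 1.0


# ---------------------------------------------------------------------------
# Hausdorff distances

def _dense_points_and_line(curve: PlanarCurve, densify_m: float):
    pts = densify(curve, densify_m)
    ring = np.vstack([curve.vertices, curve.vertices[:1]]) if curve.closed else curve.vertices
    return pts, shapely.linestrings(ring)


def _directed_distances(pts: np.ndarray, line) -> np.ndarray:
    return shapely.distance(shapely.points(pts), line)


def hausdorff_max(
    a: PlanarCurve, b: PlanarCurve, densify_m: float = DEFAULT_DENSIFY_M
) -> float:
    """Classical symmetric Hausdorff distance between two curves (meters)."""
    pa, la = _dense_points_and_line(a, densify_m)
    pb, lb = _dense_points_and_line(b, densify_m)
    return float(max(_directed_distances(pa, lb).max(),
                     _directed_distances(pb, la).max()))


def hausdorff_mean(
    a: PlanarCurve, b: PlanarCurve, densify_m: float = DEFAULT_DENSIFY_M
) -> float:
    """Symmetrized arclength-weighted mean point-to-curve distance (meters)."""
    means = []
    for src, dst in ((a, b), (b, a)):
        pts, _ = _dense_points_and_line(src, densify_m)
        _, line = _dense_points_and_line(dst, densify_m)
        d = _directed_distances(pts, line)
        # weight each sample by the arclength it represents (half of the two
        # adjacent edges; wraps for closed curves)
        ring = np.vstack([pts, pts[:1]]) if src.closed else pts
        edges = np.linalg.norm(np.diff(ring, axis=0), axis=1)
        if src.closed:
            w = 0.5 * (edges + np.roll(edges, 1))
        else:
            w = np.zeros(len(pts))
            w[:-1] += 0.5 * edges
            w[1:] += 0.5 * edges
        means.append(float(np.average(d, weights=w)))
    return 0.5 * (means[0] + means[1])


# ---------------------------------------------------------------------------
# distance report (per-habitat aggregation)

@dataclass
class DistanceRow:
    habitat_code: str
    segment_label: str
    mean_hausdorff_m: float
    max_hausdorff_m: float


@dataclass
class DistanceReport:
    rows: list[DistanceRow]
    habitat_averages: dict[str, tuple[float, float]] = field(default_factory=dict)
    overall_average: tuple[float, float] = (np.nan, np.nan)

    @classmethod
    def from_rows(cls, rows: Sequence[DistanceRow]) -> "DistanceReport":
        rows = list(rows)
        if not rows:
            raise ValueError("empty distance report")
        hab: dict[str, tuple[float, float]] = {}
        for code in dict.fromkeys(r.habitat_code for r in rows):
            sub = [r for r in rows if r.habitat_code == code]
            hab[code] = (
                float(np.mean([r.mean_hausdorff_m for r in sub])),
                float(np.mean([r.max_hausdorff_m for r in sub])),
            )
        overall = (
            float(np.mean([r.mean_hausdorff_m for r in rows])),
            float(np.mean([r.max_hausdorff_m for r in rows])),
        )
        return cls(rows=rows, habitat_averages=hab, overall_average=overall)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (r.habitat_code, r.segment_label, r.mean_hausdorff_m, r.max_hausdorff_m)
            for r in self.rows
        ]
        for code, (m, mx) in self.habitat_averages.items():
            recs.append((code, "Habitat average", m, mx))
        recs.append(("", "Average overall", *self.overall_average))
        return pd.DataFrame(
            recs,
            columns=["habitat", "segment", "mean_hausdorff_m", "max_hausdorff_m"],
        )


def build_distance_report(
    pairs: Sequence[tuple[str, str, PlanarCurve, PlanarCurve]],
    densify_m: float = DEFAULT_DENSIFY_M,
) -> DistanceReport:
    """Per-pair mean/max Hausdorff distances with habitat and overall averages."""
    rows = [
        DistanceRow(
            habitat_code=code,
            segment_label=label,
            mean_hausdorff_m=hausdorff_mean(seg, gps, densify_m),
            max_hausdorff_m=hausdorff_max(seg, gps, densify_m),
        )
        for code, label, seg, gps in pairs
    ]
    return DistanceReport.from_rows(rows)


def load_distance_table(path: str | Path) -> DistanceReport:
    """Aggregate a CSV of precomputed per-segment distances
    (columns habitat, segment, mean_hausdorff_m, max_hausdorff_m)."""
    df = pd.read_csv(path, dtype={"habitat": str, "segment": str})
    rows = [
        DistanceRow(r.habitat, str(r.segment), float(r.mean_hausdorff_m),
                    float(r.max_hausdorff_m))
        for r in df.itertuples()
    ]
    return DistanceReport.from_rows(rows)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class FeatureMatrix:
    """Numeric feature table with one group label per row."""

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.group = pd.Series(self.group).reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.values) != len(self.group):
            raise ValueError("group labels must align with rows")
        counts = self.group.value_counts()
        if len(counts) < 2:
            raise ValueError("need >= 2 groups")
        if (counts < 2).any():
            raise ValueError(f"every group needs >= 2 rows, got {counts.to_dict()}")


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    distance: str
    degenerate: bool = False


def _distance_matrix(fm: FeatureMatrix, distance: str) -> np.ndarray:
    x = fm.values.to_numpy(dtype=float)
    if distance == "euclidean":
        # z-score columns so heterogeneous units contribute comparably
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=0)) / sd
        return squareform(pdist(z, metric="euclidean"))
    if distance == "bray_curtis":
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = hi - lo
        span[span == 0] = 1.0
        scaled = (x - lo) / span  # Bray-Curtis needs nonnegative features
        return squareform(pdist(scaled, metric="braycurtis"))
    raise ValueError(f"unknown distance {distance!r}")


def _pseudo_f_batch(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    """Pseudo-F from the squared-distance matrix for one labelling."""
    n = d2.shape[0]
    a = len(group_indices)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = sum(
        d2[np.ix_(ix, ix)][np.triu_indices(len(ix), 1)].sum() / len(ix)
        for ix in group_indices
    )
    ss_among = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom <= 0:
        return np.inf
    return (ss_among / (a - 1)) / denom


def permanova(
    features: FeatureMatrix,
    distance: str = "euclidean",
    n_permutations: int = 9_999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a pairwise distance matrix.

    The pseudo-F statistic partitions the sums of squared inter-point
    distances by group; the p-value uses label permutation with the +1
    correction: p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    dm = _distance_matrix(features, distance)
    d2 = dm**2
    labels = features.group.to_numpy()
    codes, inverse = np.unique(labels, return_inverse=True)
    sizes = [int((inverse == k).sum()) for k in range(len(codes))]
    n = len(labels)

    if not np.any(dm[np.triu_indices(n, 1)] > 0):
        return PermanovaResult(np.nan, np.nan, 0, distance, degenerate=True)

    obs_idx = [np.flatnonzero(inverse == k) for k in range(len(codes))]
    f_obs = _pseudo_f_batch(d2, obs_idx)

    rng = np.random.default_rng(seed)
    # batch-evaluate permutations: within-group sums via advanced indexing
    exceed = 0
    batch = 2_000
    done = 0
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        ss_within = np.zeros(m)
        start = 0
        for sz in sizes:
            ix = perms[:, start:start + sz]
            block = d2[ix[:, :, None], ix[:, None, :]]
            ss_within += block.sum(axis=(1, 2)) / (2.0 * sz)
            start += sz
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_among = ss_total - ss_within
        a = len(codes)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_among / (a - 1)) / (ss_within / (n - a))
        exceed += int(np.sum(f_perm >= f_obs - 1e-12))
        done += m
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, distance)


def band_combination_screen(
    features: FeatureMatrix,
    stat_subsets: dict[str, Sequence[str]],
    distance: str = "euclidean",
    n_permutations: int = 9_999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run PERMANOVA per named column subset; sorted by p then F."""
    rows = []
    for name, cols in stat_subsets.items():
        cols = list(cols)
        if not cols:
            raise ValueError(f"empty column subset {name!r}")
        missing = [c for c in cols if c not in features.values.columns]
        if missing:
            raise ValueError(f"unknown columns in subset {name!r}: {missing}")
        sub = FeatureMatrix(features.values[cols], features.group)
        res = permanova(sub, distance, n_permutations, seed)
        rows.append((name, res.pseudo_f, res.p_value))
    df = pd.DataFrame(rows, columns=["subset", "pseudo_F", "p_value"])
    return df.sort_values(["p_value", "pseudo_F"], ascending=[True, False]).reset_index(
        drop=True
    )
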