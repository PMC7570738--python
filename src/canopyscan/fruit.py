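"""Fruit detection and weight estimation from colored canopy point clouds.

Mature fruits are the only strongly red (tomato) or yellow-orange
(paprika) surfaces in a vegetative canopy, so a fixed RGB gate —
tomato R>140, G<100, B<100; paprika R>150, G>110, B<50, all strict —
isolates fruit points. Gated points are grouped into per-fruit instances
by density clustering, each instance is voxelised with its interior
flood-filled to form a solid, and weight follows as

    W (g) = voxel volume (cm³) × fruit density (g/cm³)

with densities of 0.84 g/cm³ for tomato and 0.59 g/cm³ for paprika.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from canopyscan.io_formats import (
    ColoredPointCloud,
    RGBGate,
    SpeciesParams,
    SpeciesConfigError,
)

__all__ = [
    "RGBGate",
    "FruitCluster",
    "FruitEstimate",
    "DegenerateClusterError",
    "gate_points",
    "cluster_fruit_points",
    "voxel_volume",
    "estimate_fruit_weight",
    "canopy_yield",
]

logger = logging.getLogger(__name__)


class DegenerateClusterError(ValueError):
    """Cluster points are collinear or coplanar; no solid can be formed."""


@dataclass(frozen=True)
class FruitCluster:
    """One detected fruit instance: indices into the source cloud."""

    point_indices: np.ndarray
    centroid: np.ndarray  # (3,) cm

    @property
    def point_count(self) -> int:
        return len(self.point_indices)


@dataclass(frozen=True)
class FruitEstimate:
    """Volume and weight estimate for one fruit cluster."""

    cluster: FruitCluster
    volume: float  # cm³
    weight: float  # g
    voxel_size: float  # cm


def gate_points(cloud: ColoredPointCloud, gate: RGBGate) -> ColoredPointCloud:
    """Keep exactly the points whose color passes every stated gate bound.

    All bounds are strict inequalities (R > r_min, R < r_max, ...), and
    point order is preserved. An empty result is legitimate — a canopy
    with no mature fruit.
    """
    keep = gate.mask(cloud.colors)
    return ColoredPointCloud(
        points=cloud.points[keep],
        colors=cloud.colors[keep],
        source_unit=cloud.source_unit,
    )


def cluster_fruit_points(
    cloud: ColoredPointCloud, eps: float = 2.0, min_points: int = 50
) -> list[FruitCluster]:
    """Group gated fruit points into instances by Euclidean proximity.

    Clusters are the connected components of the eps-neighborhood graph
    (two points link when within ``eps`` cm), so the partition is
    independent of point order. Components with fewer than ``min_points``
    members are discarded as drift noise — stray gated points such as
    blushing unripe fruit never reach fruit-sized clusters.

    Returns clusters sorted by centroid (x, then y, then z) for a
    deterministic report order.
    """
    if not eps > 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if min_points < 1:
        raise ValueError(f"min_points must be >= 1, got {min_points}")
    n = len(cloud)
    if n == 0:
        return []

    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(r=eps, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)

    clusters = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < min_points:
            continue
        clusters.append(
            FruitCluster(
                point_indices=idx,
                centroid=cloud.points[idx].mean(axis=0),
            )
        )
    clusters.sort(key=lambda c: tuple(c.centroid))
    return clusters


def voxel_volume(points: np.ndarray, voxel_size: float = 0.5) -> float:
    """Solid volume (cm³) of a point shell by voxel counting.

    The cluster's bounding box is rasterised into cubic cells of edge
    ``voxel_size``; cells containing points are occupied. The exterior is
    flood-filled inward from the box boundary with 6-connectivity, and
    every unreached empty cell counts as interior — the voxel equivalent
    of converting a closed surface to a solid model. Interior cells count
    fully; occupied (shell) cells straddle the true surface, so they
    count half — the midpoint rule that removes the outward half-cell
    bias of counting crossed cells whole:

        volume = (interior + occupied / 2) × voxel_size³

    Raises
    ------
    DegenerateClusterError
        Fewer than 4 points, or all points coplanar/collinear: no
        interior exists. Either reject the cluster or rescan.
    """
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateClusterError(
            f"need >= 4 points to enclose a volume, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateClusterError(
            "points are coplanar or collinear; increase voxel_size or "
            "reject this cluster"
        )

    lo = pts.min(axis=0)
    extent = pts.max(axis=0) - lo
    dims = np.maximum(np.ceil(extent / voxel_size).astype(int), 1)
    idx = np.minimum((pts - lo) // voxel_size, dims - 1).astype(int)

    # one empty cell of padding so the exterior flood reaches all sides
    grid = np.zeros(dims + 2, dtype=bool)
    grid[idx[:, 0] + 1, idx[:, 1] + 1, idx[:, 2] + 1] = True

    # 6-connected components of empty space; the component touching the
    # padding ring is outside the fruit
    empty_labels, _ = ndimage.label(~grid)  # default structure = 6-connectivity
    exterior_label = empty_labels[0, 0, 0]
    interior = (~grid) & (empty_labels != exterior_label)

    n_shell = int(grid.sum())
    n_interior = int(interior.sum())
    return (n_interior + 0.5 * n_shell) * voxel_size**3


def estimate_fruit_weight(volume: float, params: SpeciesParams) -> float:
    """Fruit fresh weight (g) = volume (cm³) × species density (g/cm³)."""
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    if params.fruit_density is None:
        raise SpeciesConfigError(
            f"species {params.name!r} has no fruit_density defined"
        )
    return volume * params.fruit_density


def canopy_yield(
    cloud: ColoredPointCloud,
    params: SpeciesParams,
    eps: float = 2.0,
    min_points: int = 50,
    voxel_size: float = 0.5,
    gate: Optional[RGBGate] = None,
) -> tuple[list[FruitEstimate], float]:
    """Full yield pipeline: gate, cluster, voxelise, weigh, total.

    Degenerate clusters (too flat to enclose a volume) are skipped with
    a warning rather than failing the run. Returns the per-fruit
    estimates and the summed canopy fruit weight in grams.

    Parameters
    ----------
    cloud : ColoredPointCloud
        Canopy scan with RGB colors.
    params : SpeciesParams
        Must define ``fruit_density`` and (unless ``gate`` overrides it)
        ``rgb_gate``.
    gate : RGBGate, optional
        Override the species gate, e.g. to tighten thresholds for a
        different lighting setup.
    """
    if params.fruit_density is None:
        raise SpeciesConfigError(
            f"species {params.name!r} has no fruit_density; "
            "yield estimation needs one"
        )
    effective_gate = gate if gate is not None else params.rgb_gate
    if effective_gate is None:
        raise SpeciesConfigError(
            f"species {params.name!r} has no RGB gate; yield estimation "
            "needs one"
        )

    fruit_points = gate_points(cloud, effective_gate)
    logger.info(
        "gated %d of %d points", len(fruit_points), len(cloud)
    )
    clusters = cluster_fruit_points(fruit_points, eps=eps, min_points=min_points)
    logger.info("found %d fruit clusters", len(clusters))

    estimates: list[FruitEstimate] = []
    for cluster in clusters:
        try:
            vol = voxel_volume(
                fruit_points.points[cluster.point_indices], voxel_size
            )
        except DegenerateClusterError as exc:
            logger.warning(
                "skipping cluster at %s (%d points): %s",
                np.round(cluster.centroid, 1),
                cluster.point_count,
                exc,
            )
            continue
        estimates.append(
            FruitEstimate(
                cluster=cluster,
                volume=vol,
                weight=estimate_fruit_weight(vol, params),
                voxel_size=voxel_size,
            )
        )
    total = float(sum(e.weight for e in estimates))
    return estimates, total
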