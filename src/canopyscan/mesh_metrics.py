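"""Surface-area integration and geometric cleanup for triangle meshes.

The area of one triangle with corners O, A, B is half the magnitude of
the cross product of the edge vectors OA and OB:

    area = 1/2 * |(A - O) x (B - O)|

Summing this over every polygon of a trimmed plant surface model gives
the estimated leaf area. Cropping and small-component removal replace
the manual trimming step that scan-derived models otherwise need.
"""

from __future__ import annotations

import logging
from typing import Sequence, Union

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from canopyscan.io_formats import TriangleMesh

__all__ = [
    "triangle_area",
    "triangle_areas",
    "triangle_centroids",
    "total_surface_area",
    "crop_mesh",
    "component_labels",
    "remove_small_components",
    "concatenate_meshes",
]

logger = logging.getLogger(__name__)

ArrayLike3 = Union[Sequence[float], np.ndarray]


def triangle_area(p0: ArrayLike3, p1: ArrayLike3, p2: ArrayLike3) -> float:
    """Area of the triangle (p0, p1, p2) in cm².

    Edge vectors are anchored at the first vertex; the result is half the
    cross-product magnitude, so degenerate (collinear) triangles return 0.
    Invariant to cyclic vertex permutation, winding flips, and rigid motion.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    a = np.asarray(p1, dtype=np.float64) - p0
    b = np.asarray(p2, dtype=np.float64) - p0
    if not (np.isfinite(a).all() and np.isfinite(b).all() and np.isfinite(p0).all()):
        raise ValueError("triangle vertices must be finite")
    return 0.5 * float(np.linalg.norm(np.cross(a, b)))


def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-triangle areas (cm²) for a whole mesh, vectorised."""
    if mesh.n_triangles == 0:
        return np.zeros(0, dtype=np.float64)
    corners = mesh.triangle_vertices()  # (T, 3, 3)
    a = corners[:, 1] - corners[:, 0]
    b = corners[:, 2] - corners[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def triangle_centroids(mesh: TriangleMesh) -> np.ndarray:
    """Per-triangle centroid coordinates, (T, 3) in cm."""
    if mesh.n_triangles == 0:
        return np.zeros((0, 3), dtype=np.float64)
    return mesh.triangle_vertices().mean(axis=1)


def total_surface_area(mesh: TriangleMesh) -> float:
    """Sum of all polygon areas of the mesh, cm².

    Additive under mesh concatenation; an empty mesh contributes 0 (with
    a logged warning, since it usually signals an upstream trimming
    mistake).
    """
    if mesh.n_triangles == 0:
        logger.warning("total_surface_area: empty mesh, returning 0")
        return 0.0
    return float(triangle_areas(mesh).sum())


def crop_mesh(mesh: TriangleMesh, bounding_box: ArrayLike3) -> TriangleMesh:
    """Keep the triangles whose centroid falls inside an axis-aligned box.

    The box is ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]`` and is
    half-open: min <= centroid < max per axis, so boxes that tile space
    partition the triangles exactly. Triangles are never split.
    """
    box = np.asarray(bounding_box, dtype=np.float64).reshape(2, 3)
    if not (box[0] < box[1]).all():
        raise ValueError(f"inverted bounding box: min {box[0]} !< max {box[1]}")
    if mesh.n_triangles == 0:
        return TriangleMesh(vertices=mesh.vertices.copy(), triangles=np.zeros((0, 3), dtype=np.int64))
    c = triangle_centroids(mesh)
    keep = ((c >= box[0]) & (c < box[1])).all(axis=1)
    return _subset(mesh, keep)


def _subset(mesh: TriangleMesh, keep: np.ndarray) -> TriangleMesh:
    """New mesh holding only the selected triangles (vertices compacted)."""
    tris = mesh.triangles[keep]
    if tris.size == 0:
        return TriangleMesh(
            vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=np.int64)
        )
    used, inverse = np.unique(tris, return_inverse=True)
    return TriangleMesh(
        vertices=mesh.vertices[used],
        triangles=inverse.reshape(-1, 3),
    )


def component_labels(mesh: TriangleMesh) -> tuple[int, np.ndarray]:
    """Edge-connected component count and per-triangle labels.

    Vertices are first welded by exact coordinate match so triangle-soup
    meshes (e.g. STL facets) regain connectivity; two triangles then
    belong to one component when they share an undirected vertex-pair
    edge.
    """
    if mesh.n_triangles == 0:
        return 0, np.zeros(0, dtype=np.int64)

    _, canon = np.unique(mesh.vertices, axis=0, return_inverse=True)
    tris = canon[mesh.triangles]  # (T, 3) canonical vertex ids

    edges = np.sort(
        np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]),
        axis=1,
    )
    tri_ids = np.tile(np.arange(mesh.n_triangles), 3)
    # group triangles by shared edge, then link consecutive members
    _, edge_group = np.unique(edges, axis=0, return_inverse=True)
    order = np.argsort(edge_group, kind="stable")
    sorted_groups = edge_group[order]
    sorted_tris = tri_ids[order]
    same = sorted_groups[1:] == sorted_groups[:-1]
    rows = sorted_tris[:-1][same]
    cols = sorted_tris[1:][same]

    graph = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(mesh.n_triangles, mesh.n_triangles),
    )
    return connected_components(graph, directed=False)


def remove_small_components(mesh: TriangleMesh, min_area: float) -> TriangleMesh:
    """Drop edge-connected mesh components whose total area is below a floor.

    An automated stand-in for manually trimming the small floating
    polygon patches that scanner drift noise produces: any component
    (see `component_labels`) whose summed triangle area falls below
    ``min_area`` (cm²) is removed.
    """
    if min_area < 0:
        raise ValueError(f"min_area must be >= 0, got {min_area}")
    if mesh.n_triangles == 0 or min_area == 0:
        return mesh

    n_comp, labels = component_labels(mesh)
    areas = triangle_areas(mesh)
    comp_area = np.bincount(labels, weights=areas, minlength=n_comp)
    keep = comp_area[labels] >= min_area
    return _subset(mesh, keep)


def concatenate_meshes(meshes: Sequence[TriangleMesh]) -> TriangleMesh:
    """Stack several meshes into one (disjoint union, no welding)."""
    meshes = [m for m in meshes if m.n_triangles > 0]
    if not meshes:
        return TriangleMesh(
            vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=np.int64)
        )
    verts = []
    tris = []
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        tris.append(m.triangles + offset)
        offset += len(m.vertices)
    return TriangleMesh(
        vertices=np.concatenate(verts), triangles=np.concatenate(tris)
    )
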