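"""Synthetic plants, canopies, and fruit scenes with exact ground truth.

No scan archive ships with the package, so every estimator is validated
against generated scenes whose true quantities are known analytically:

* plants are a thin triangulated stem plus planar elliptical leaves, so
  each leaf's true area is the shoelace area of its polygon — exact, not
  a quadrature;
* canopies place plants on the zigzag bench layout used in greenhouse
  benches (default six plants, 33 cm apart) and record the cultivation
  footprint;
* fruit scenes sample dense shell points on spheres colored inside the
  species RGB gate, plus foliage points colored provably outside both
  gates, so gating is exact rather than statistical; true fruit volume
  is 4/3 π r³.

Stem area is tracked separately from leaf area in the ground truth, so
tests can quantify how much the stem contaminates a "leaf area" read
off the whole model — the same bias a field regression silently absorbs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from canopyscan.io_formats import ColoredPointCloud, RGBGate, TriangleMesh, default_species
from canopyscan.mesh_metrics import concatenate_meshes, total_surface_area

__all__ = [
    "SceneGroundTruth",
    "generate_plant",
    "generate_canopy",
    "generate_fruit_scene",
]

# species-typical mature leaf dimensions, cm (mean length, sd, width/length)
_LEAF_GEOMETRY = {
    "tomato": (25.0, 5.0, 0.65),
    "cucumber": (20.0, 3.0, 1.0),
    "paprika": (10.0, 2.0, 0.5),
}

_STEM_RADIUS_CM = 0.6
_LEAF_POLYGON_SIDES = 16
_MAX_LEAF_TILT_RAD = np.deg2rad(30.0)


@dataclass
class SceneGroundTruth:
    """Exact truths for one generated scene.

    Totals are sums of the recorded parts; ``stem_area`` is excluded
    from ``total_leaf_area``.
    """

    seed: int
    leaf_areas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    total_leaf_area: float = 0.0  # cm²
    stem_area: float = 0.0  # cm²
    plant_heights: list[float] = field(default_factory=list)  # cm
    cultivation_area: Optional[float] = None  # m²
    lai: Optional[float] = None  # leaves only
    fruit_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    fruit_radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fruit_volumes: np.ndarray = field(default_factory=lambda: np.zeros(0))  # cm³
    plants: list["SceneGroundTruth"] = field(default_factory=list)


def _shoelace_area(xy: np.ndarray) -> float:
    """Exact area of a simple 2D polygon."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _leaf_mesh(
    attach: np.ndarray,
    length: float,
    width: float,
    azimuth: float,
    tilt: float,
) -> tuple[TriangleMesh, float]:
    """One planar elliptical leaf as a triangle fan; returns (mesh, area).

    The leaf plane is spanned by the length axis ``u`` (tilted upward by
    ``tilt`` from horizontal, pointing along ``azimuth``) and the
    horizontal width axis ``v``; the ellipse midpoint sits half a length
    out from the attachment point, so the leaf's z range is exactly
    [attach_z, attach_z + length·sin(tilt)].
    """
    u = np.array(
        [np.cos(azimuth) * np.cos(tilt), np.sin(azimuth) * np.cos(tilt), np.sin(tilt)]
    )
    v = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    center = attach + u * (length / 2.0)

    theta = 2.0 * np.pi * np.arange(_LEAF_POLYGON_SIDES) / _LEAF_POLYGON_SIDES
    loc_x = (length / 2.0) * np.cos(theta)
    loc_y = (width / 2.0) * np.sin(theta)
    ring = center + np.outer(loc_x, u) + np.outer(loc_y, v)

    area = _shoelace_area(np.column_stack([loc_x, loc_y]))

    vertices = np.vstack([center, ring])
    k = _LEAF_POLYGON_SIDES
    tris = np.column_stack(
        [np.zeros(k, dtype=np.int64), np.arange(1, k + 1), np.roll(np.arange(1, k + 1), -1)]
    )
    return TriangleMesh(vertices=vertices, triangles=tris), area


def _stem_mesh(height: float, base: np.ndarray, n_sides: int = 8) -> TriangleMesh:
    """Open triangulated cylinder from the base to the growing point."""
    theta = 2.0 * np.pi * np.arange(n_sides) / n_sides
    ring = np.column_stack(
        [_STEM_RADIUS_CM * np.cos(theta), _STEM_RADIUS_CM * np.sin(theta), np.zeros(n_sides)]
    )
    bottom = base + ring
    top = bottom + np.array([0.0, 0.0, height])
    vertices = np.vstack([bottom, top])
    i = np.arange(n_sides, dtype=np.int64)
    j = (i + 1) % n_sides
    lower = np.column_stack([i, j, i + n_sides])
    upper = np.column_stack([j, j + n_sides, i + n_sides])
    return TriangleMesh(vertices=vertices, triangles=np.vstack([lower, upper]))


def generate_plant(
    species: str = "tomato",
    n_leaves: int = 15,
    height: float = 120.0,
    seed: int = 0,
    base: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[TriangleMesh, SceneGroundTruth]:
    """Generate one synthetic plant mesh with exact per-leaf areas.

    The stem spans z ∈ [base_z, base_z + height] so the mesh z extent is
    the requested height exactly; leaves attach along the stem and never
    rise above the growing point. Leaf sizes are drawn from a seeded
    species-typical distribution.
    """
    if n_leaves < 1:
        raise ValueError(f"n_leaves must be >= 1, got {n_leaves}")
    if not height > 0:
        raise ValueError(f"height must be positive, got {height}")
    if species not in _LEAF_GEOMETRY:
        raise ValueError(
            f"unknown species {species!r}; choose from {sorted(_LEAF_GEOMETRY)}"
        )

    rng = np.random.default_rng(seed)
    base = np.asarray(base, dtype=np.float64)
    mean_len, sd_len, width_ratio = _LEAF_GEOMETRY[species]

    stem = _stem_mesh(height, base)
    meshes = [stem]
    leaf_areas = []
    for _ in range(n_leaves):
        length = float(np.clip(rng.normal(mean_len, sd_len), 0.3 * mean_len, 2.0 * mean_len))
        width = length * width_ratio
        tilt = float(rng.uniform(0.0, _MAX_LEAF_TILT_RAD))
        azimuth = float(rng.uniform(0.0, 2.0 * np.pi))
        rise = length * np.sin(tilt)
        lo = 0.05 * height
        hi = max(lo + 1e-6, height - rise)
        attach_z = float(rng.uniform(lo, hi))
        attach = base + np.array([0.0, 0.0, attach_z])
        leaf, area = _leaf_mesh(attach, length, width, azimuth, tilt)
        meshes.append(leaf)
        leaf_areas.append(area)

    mesh = concatenate_meshes(meshes)
    truth = SceneGroundTruth(
        seed=seed,
        leaf_areas=np.asarray(leaf_areas),
        total_leaf_area=float(np.sum(leaf_areas)),
        stem_area=total_surface_area(stem),
        plant_heights=[height],
    )
    return mesh, truth


def generate_canopy(
    species: str = "tomato",
    n_plants: int = 6,
    spacing: float = 33.0,
    height: float = 120.0,
    n_leaves: int = 15,
    seed: int = 0,
) -> tuple[TriangleMesh, SceneGroundTruth]:
    """Generate a canopy of plants on a zigzag bench layout.

    Plants occupy two staggered rows ``spacing`` cm apart (the zigzag),
    each with a seeded height jitter of ±10 %. The cultivation area is
    the layout bounding box padded by half a spacing per side, in m²,
    and the ground-truth LAI uses leaf areas only (no stem).
    """
    if n_plants < 1:
        raise ValueError(f"n_plants must be >= 1, got {n_plants}")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_plants)

    positions = []
    for i in range(n_plants):
        row, col = i % 2, i // 2
        positions.append((col * spacing + 0.5 * row * spacing, row * spacing))
    positions = np.asarray(positions, dtype=np.float64)

    meshes = []
    sub_truths = []
    for i in range(n_plants):
        h = height * float(rng.uniform(0.9, 1.1))
        mesh_i, truth_i = generate_plant(
            species=species,
            n_leaves=n_leaves,
            height=h,
            seed=int(child_seeds[i]),
            base=(positions[i, 0], positions[i, 1], 0.0),
        )
        meshes.append(mesh_i)
        sub_truths.append(truth_i)

    span = positions.max(axis=0) - positions.min(axis=0) + spacing
    cultivation_area_m2 = float(span[0] * span[1]) * 1e-4

    total_leaf = float(sum(t.total_leaf_area for t in sub_truths))
    truth = SceneGroundTruth(
        seed=seed,
        leaf_areas=np.concatenate([t.leaf_areas for t in sub_truths]),
        total_leaf_area=total_leaf,
        stem_area=float(sum(t.stem_area for t in sub_truths)),
        plant_heights=[t.plant_heights[0] for t in sub_truths],
        cultivation_area=cultivation_area_m2,
        lai=(total_leaf * 1e-4) / cultivation_area_m2,
        plants=sub_truths,
    )
    return concatenate_meshes(meshes), truth


def _gate_color_sampler(gate: RGBGate, rng: np.random.Generator):
    """Uniform integer colors strictly inside every stated gate bound."""
    los = [
        (gate.r_min + 1) if gate.r_min is not None else 0,
        (gate.g_min + 1) if gate.g_min is not None else 0,
        (gate.b_min + 1) if gate.b_min is not None else 0,
    ]
    his = [
        (gate.r_max - 1) if gate.r_max is not None else 255,
        (gate.g_max - 1) if gate.g_max is not None else 255,
        (gate.b_max - 1) if gate.b_max is not None else 255,
    ]

    def sample(n: int) -> np.ndarray:
        return np.column_stack(
            [rng.integers(lo, hi + 1, size=n) for lo, hi in zip(los, his)]
        )

    return sample


def _foliage_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Leafy greens chosen strictly outside both species gates.

    R < 140 fails the tomato gate (R > 140) and the paprika gate
    (R > 150) outright, so no foliage point can ever pass either.
    """
    r = rng.integers(20, 140, size=n)
    g = rng.integers(121, 256, size=n)
    b = rng.integers(20, 101, size=n)
    return np.column_stack([r, g, b])


def _sphere_shell(
    center: np.ndarray, radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points on a sphere surface (normal-deviate method)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v


def generate_fruit_scene(
    species: str = "tomato",
    fruit_specs: Optional[Sequence[tuple[Sequence[float], float]]] = None,
    foliage_points: int = 20000,
    noise_fraction: float = 0.0,
    seed: int = 0,
    points_per_cm2: float = 40.0,
    hemisphere_dropout: bool = False,
) -> tuple[ColoredPointCloud, SceneGroundTruth]:
    """Generate a fruit-bearing canopy point cloud with known fruit volumes.

    Parameters
    ----------
    species : {"tomato", "paprika"}
        Determines the gate the fruit colors are sampled inside.
    fruit_specs : sequence of ((x, y, z), radius), optional
        Fruit placements in cm; must not overlap. Default: five fruits
        of radius 3–4 cm scattered without overlap over a 150 cm canopy
        slab.
    foliage_points : int
        Leaf-colored clutter points scattered over the canopy volume.
    noise_fraction : float
        Extra points with fully random colors and positions, as a
        fraction of the total so far (scanner color noise).
    points_per_cm2 : float
        Shell sampling density on each fruit; the default oversamples a
        0.5 cm voxel grid several-fold so solids close.
    hemisphere_dropout : bool
        Drop every shell point on each fruit's far side (y > center_y),
        emulating the occluded back that a single-side scan misses.
    """
    table = default_species()
    if species not in table or table[species].rgb_gate is None:
        raise ValueError(f"no fruit gate defined for species {species!r}")
    gate = table[species].rgb_gate
    rng = np.random.default_rng(seed)

    if fruit_specs is None:
        fruit_specs = []
        tries = 0
        while len(fruit_specs) < 5 and tries < 1000:
            tries += 1
            c = rng.uniform([20, 20, 30], [180, 60, 130])
            r = float(rng.uniform(3.0, 4.0))
            if all(
                np.linalg.norm(c - np.asarray(c2)) > r + r2 + 2.0
                for c2, r2 in fruit_specs
            ):
                fruit_specs.append((c, r))

    centers = np.asarray([np.asarray(c, dtype=np.float64) for c, _ in fruit_specs])
    radii = np.asarray([float(r) for _, r in fruit_specs])
    if (radii <= 0).any():
        raise ValueError("fruit radii must be positive")
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                raise ValueError(f"fruits {i} and {j} overlap")

    color_sampler = _gate_color_sampler(gate, rng)

    pts_list = []
    col_list = []
    for c, r in zip(centers, radii):
        n = max(200, int(4.0 * np.pi * r * r * points_per_cm2))
        shell = _sphere_shell(c, r, n, rng)
        if hemisphere_dropout:
            shell = shell[shell[:, 1] <= c[1]]
        pts_list.append(shell)
        col_list.append(color_sampler(len(shell)))

    if foliage_points > 0:
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([200.0, 80.0, 150.0])
        pts_list.append(rng.uniform(lo, hi, size=(foliage_points, 3)))
        col_list.append(_foliage_colors(foliage_points, rng))

    points = np.concatenate(pts_list) if pts_list else np.zeros((0, 3))
    colors = np.concatenate(col_list) if col_list else np.zeros((0, 3), dtype=int)

    if noise_fraction > 0:
        n_noise = int(noise_fraction * len(points))
        noise_pts = rng.uniform([0, 0, 0], [200, 80, 150], size=(n_noise, 3))
        noise_cols = rng.integers(0, 256, size=(n_noise, 3))
        points = np.concatenate([points, noise_pts])
        colors = np.concatenate([colors, noise_cols])

    cloud = ColoredPointCloud(points=points, colors=colors, source_unit="cm")
    truth = SceneGroundTruth(
        seed=seed,
        fruit_centers=centers,
        fruit_radii=radii,
        fruit_volumes=(4.0 / 3.0) * np.pi * radii**3,
    )
    return cloud, truth
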