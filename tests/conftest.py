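"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from canopyscan.io_formats import ColoredPointCloud, TriangleMesh


def heron_area(p0, p1, p2) -> float:
    """Triangle area from side lengths (Kahan's numerically stable Heron).

    Independent of the cross-product route: uses only pairwise distances.
    """
    a = float(np.linalg.norm(np.subtract(p1, p0)))
    b = float(np.linalg.norm(np.subtract(p2, p0)))
    c = float(np.linalg.norm(np.subtract(p2, p1)))
    a, b, c = sorted((a, b, c), reverse=True)  # a >= b >= c
    term = (a + (b + c)) * (c - (a - b)) * (c + (a - b)) * (a + (b - c))
    return 0.25 * math.sqrt(max(term, 0.0))


def shoelace_area(xy: np.ndarray) -> float:
    """Exact area of a simple 2D polygon by the shoelace formula."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sphere_shell_points(
    center, radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points on a sphere surface."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center, dtype=float) + radius * v


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200915)


@pytest.fixture
def unit_cube_mesh() -> TriangleMesh:
    """Axis-aligned unit cube as 12 triangles; surface area 6 cm²."""
    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
        dtype=float,
    )
    # index layout: bit 2 = x, bit 1 = y, bit 0 = z
    faces = [
        (0, 1, 3), (0, 3, 2),  # x = 0
        (4, 7, 5), (4, 6, 7),  # x = 1
        (0, 5, 1), (0, 4, 5),  # y = 0
        (2, 3, 7), (2, 7, 6),  # y = 1
        (0, 2, 6), (0, 6, 4),  # z = 0
        (1, 5, 7), (1, 7, 3),  # z = 1
    ]
    return TriangleMesh(vertices=v, triangles=np.array(faces))


@pytest.fixture
def two_leaf_mesh() -> TriangleMesh:
    """Two separated unit right triangles ('leaves'), 30 cm apart in x."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [0, 1, 0],
            [30, 0, 0], [31, 0, 0], [30, 1, 0],
        ],
        dtype=float,
    )
    t = np.array([[0, 1, 2], [3, 4, 5]])
    return TriangleMesh(vertices=v, triangles=t)


@pytest.fixture
def random_cloud(rng) -> ColoredPointCloud:
    n = 500
    return ColoredPointCloud(
        points=rng.uniform(-50, 50, size=(n, 3)),
        colors=rng.integers(0, 256, size=(n, 3)),
        source_unit="cm",
    )
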