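"""Growth parameters: leaf area, LAI, height, canopy structure, dry weight.

Two routes to leaf area coexist, mirroring greenhouse practice:

* allometric — ``area = a × length × width`` with a species coefficient
  ``a`` (tomato 0.25, cucumber 0.87, paprika 0.59), the non-destructive
  tape-measure route;
* geometric — integrating all polygon areas of a scanned surface model.

LAI divides canopy leaf area (m²) by the cultivation ground area (m²).
Plant height is the z extent of the trimmed model. Canopy structure is
the vertical profile of leaf area in height bins. Dry weight rides on a
linear regression against leaf area, since specific leaf area within a
species makes the two near-proportional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from canopyscan.io_formats import ColoredPointCloud, SpeciesParams, TriangleMesh
from canopyscan.mesh_metrics import (
    total_surface_area,
    triangle_areas,
    triangle_centroids,
)

__all__ = [
    "AllometricFit",
    "DryWeightModel",
    "VerticalProfile",
    "GrowthReport",
    "allometric_leaf_area",
    "fit_allometric_coefficient",
    "estimate_leaf_area",
    "estimate_lai",
    "estimate_plant_height",
    "canopy_structure",
    "fit_dry_weight_model",
    "predict_dry_weight",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AllometricFit:
    """Through-origin fit of leaf area on length × width."""

    coefficient_a: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class DryWeightModel:
    """Linear model of dry weight (g) on leaf area (cm²)."""

    slope: float
    intercept: float
    target: str  # "leaf" or "total"
    species: str
    r_squared: float


@dataclass(frozen=True)
class VerticalProfile:
    """Leaf area per height bin: the canopy's vertical structure."""

    bin_edges: np.ndarray  # (k+1,) increasing heights, cm
    bin_areas: np.ndarray  # (k,) leaf area per bin, cm²

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        areas = np.asarray(self.bin_areas, dtype=np.float64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_areas", areas)
        if edges.size and len(areas) != len(edges) - 1:
            raise ValueError("need len(bin_areas) == len(bin_edges) - 1")
        if edges.size > 1 and not (np.diff(edges) > 0).all():
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def total_area(self) -> float:
        return float(self.bin_areas.sum())


@dataclass
class GrowthReport:
    """One plant's (or canopy's) growth parameters in report form."""

    species: str
    leaf_area: float  # cm²
    plant_height: float  # cm
    lai: Optional[float] = None  # canopy runs only
    profile: Optional[VerticalProfile] = None

    def to_dict(self) -> dict:
        out = {
            "species": self.species,
            "leaf_area_cm2": self.leaf_area,
            "plant_height_cm": self.plant_height,
        }
        if self.lai is not None:
            out["lai"] = self.lai
        if self.profile is not None:
            out["profile"] = {
                "bin_edges_cm": self.profile.bin_edges.tolist(),
                "bin_areas_cm2": self.profile.bin_areas.tolist(),
            }
        return out


def allometric_leaf_area(
    length: float, width: float, params: SpeciesParams
) -> float:
    """Leaf area (cm²) from length × width (cm) and the species coefficient."""
    if not (length > 0 and width > 0):
        raise ValueError(
            f"leaf length and width must be positive, got {length}, {width}"
        )
    return params.allometric_a * length * width


def fit_allometric_coefficient(
    pairs: Union[np.ndarray, Sequence[Sequence[float]]],
) -> AllometricFit:
    """Recover the species coefficient ``a`` from (length×width, area) pairs.

    Least-squares slope through the origin of measured area on the
    length-width product, with the R² of that through-origin regression.

    Parameters
    ----------
    pairs : (n, 2) array
        Column 0: leaf length × width, cm²; column 1: measured leaf
        area, cm². All positive, n >= 2.
    """
    arr = np.asarray(pairs, dtype=np.float64).reshape(-1, 2)
    if len(arr) < 2:
        raise ValueError(f"need at least 2 leaves, got {len(arr)}")
    if not (arr > 0).all():
        raise ValueError("lengths×widths and areas must all be positive")
    x, y = arr[:, 0], arr[:, 1]
    a = float((x * y).sum() / (x * x).sum())
    resid = y - a * x
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AllometricFit(coefficient_a=a, r_squared=r2, n=len(arr))


def estimate_leaf_area(mesh: TriangleMesh, calibration: float = 1.0) -> float:
    """Leaf area (cm²) as the integrated polygon area of a trimmed model.

    ``calibration`` rescales the raw surface integral; it defaults to 1
    (areas taken as-is) and exists because reconstructed leaf sheets can
    be single- or double-sided depending on the meshing software.
    """
    return calibration * total_surface_area(mesh)


def estimate_lai(
    canopy_mesh: TriangleMesh,
    cultivation_area: float,
    calibration: float = 1.0,
) -> float:
    """Leaf area index: canopy leaf area (m²) over cultivation area (m²)."""
    if not cultivation_area > 0:
        raise ValueError(
            f"cultivation_area must be positive m², got {cultivation_area}"
        )
    leaf_area_m2 = estimate_leaf_area(canopy_mesh, calibration) * 1e-4
    return leaf_area_m2 / cultivation_area


def estimate_plant_height(
    geometry: Union[TriangleMesh, ColoredPointCloud, np.ndarray],
    base_percentile: float = 0.0,
) -> float:
    """Plant height (cm): z extent from base to growing point, z-up.

    The base is the ``base_percentile``-th percentile of vertex z
    (default 0, the minimum); a small positive percentile discounts
    residual floor points that survived trimming.
    """
    if isinstance(geometry, TriangleMesh):
        z = geometry.vertices[:, 2]
    elif isinstance(geometry, ColoredPointCloud):
        z = geometry.points[:, 2]
    else:
        z = np.asarray(geometry, dtype=np.float64).reshape(-1, 3)[:, 2]
    if z.size == 0:
        raise ValueError("cannot measure height of empty geometry")
    z_base = float(np.percentile(z, base_percentile)) if base_percentile > 0 else float(z.min())
    return float(z.max()) - z_base


def canopy_structure(mesh: TriangleMesh, bin_height: float = 10.0) -> VerticalProfile:
    """Vertical leaf-area profile: per-bin polygon area along height.

    Each triangle's full area is credited to the bin containing its
    centroid z (bins are half-open ``[lo, hi)``, the top edge closed so
    nothing is lost). Bin edges start at the mesh's z minimum and step
    ``bin_height`` cm until they cover z max; the bin areas always sum to
    the total mesh area.
    """
    if not bin_height > 0:
        raise ValueError(f"bin_height must be positive, got {bin_height}")
    if mesh.n_triangles == 0:
        return VerticalProfile(bin_edges=np.zeros(0), bin_areas=np.zeros(0))

    cz = triangle_centroids(mesh)[:, 2]
    areas = triangle_areas(mesh)
    z0 = float(mesh.vertices[:, 2].min())
    z1 = float(mesh.vertices[:, 2].max())
    n_bins = max(1, int(np.ceil((z1 - z0) / bin_height)))
    edges = z0 + bin_height * np.arange(n_bins + 1)
    idx = np.clip(((cz - z0) // bin_height).astype(int), 0, n_bins - 1)
    bin_areas = np.bincount(idx, weights=areas, minlength=n_bins)
    return VerticalProfile(bin_edges=edges, bin_areas=bin_areas)


def fit_dry_weight_model(
    pairs: Union[np.ndarray, Sequence[Sequence[float]]],
    target: str = "total",
    species: str = "",
    through_origin: bool = False,
) -> DryWeightModel:
    """Fit dry weight (g) against leaf area (cm²) by ordinary least squares.

    Parameters
    ----------
    pairs : (n, 2) array
        Column 0 leaf area cm², column 1 dry weight g; n >= 3.
    target : {"leaf", "total"}
        Which dry-weight the response is (leaf only, or leaf + stem).
    through_origin : bool
        Force a zero intercept instead of the default intercept form.
    """
    if target not in ("leaf", "total"):
        raise ValueError(f"target must be 'leaf' or 'total', got {target!r}")
    arr = np.asarray(pairs, dtype=np.float64).reshape(-1, 2)
    if len(arr) < 3:
        raise ValueError(f"need at least 3 plants, got {len(arr)}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("leaf area has zero variance; cannot fit")
    if through_origin:
        slope = float((x * y).sum() / (x * x).sum())
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return DryWeightModel(
        slope=slope,
        intercept=intercept,
        target=target,
        species=species,
        r_squared=r2,
    )


def predict_dry_weight(model: DryWeightModel, leaf_area: float) -> float:
    """Predicted dry weight (g) for a leaf area (cm²), floored at zero."""
    if leaf_area < 0:
        raise ValueError(f"leaf_area must be >= 0, got {leaf_area}")
    return max(0.0, model.slope * leaf_area + model.intercept)
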