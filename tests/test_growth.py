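"""Allometry, leaf area, LAI, plant height, canopy structure, dry weight."""

import numpy as np
import pytest

from canopyscan.growth import (
    allometric_leaf_area,
    canopy_structure,
    estimate_lai,
    estimate_leaf_area,
    estimate_plant_height,
    fit_allometric_coefficient,
    fit_dry_weight_model,
    predict_dry_weight,
)
from canopyscan.io_formats import TriangleMesh, default_species
from canopyscan.mesh_metrics import concatenate_meshes, total_surface_area
from canopyscan.synthetic import generate_canopy, generate_plant
from conftest import random_rotation


class TestAllometry:
    @pytest.mark.parametrize(
        "species, length, width, expected",
        [
            ("tomato", 20, 10, 50.0),  # a = 0.25
            ("cucumber", 10, 10, 87.0),  # a = 0.87
            ("paprika", 10, 10, 59.0),  # a = 0.59
        ],
    )
    def test_species_coefficients(self, species, length, width, expected):
        params = default_species()[species]
        assert allometric_leaf_area(length, width, params) == pytest.approx(expected)

    def test_nonpositive_dimension_rejected(self):
        params = default_species()["tomato"]
        with pytest.raises(ValueError):
            allometric_leaf_area(0, 10, params)

    def test_noiseless_fit_recovers_exactly(self, rng):
        lw = rng.uniform(50, 400, size=40)
        fit = fit_allometric_coefficient(np.column_stack([lw, 0.59 * lw]))
        assert fit.coefficient_a == pytest.approx(0.59, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 40

    @pytest.mark.parametrize("a_true", [0.25, 0.87, 0.59])
    def test_noisy_fit_recovers_within_two_percent(self, a_true):
        rng = np.random.default_rng(hash(a_true) % 2**31)
        lw = rng.uniform(50, 400, size=200)
        area = a_true * lw * rng.normal(1.0, 0.05, size=200)
        fit = fit_allometric_coefficient(np.column_stack([lw, area]))
        assert fit.coefficient_a == pytest.approx(a_true, rel=0.02)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            fit_allometric_coefficient([[100.0, 25.0]])


class TestLeafAreaAndLai:
    def test_synthetic_plant_matches_analytic_leaf_area(self):
        mesh, truth = generate_plant(n_leaves=30, height=150.0, seed=5)
        got = estimate_leaf_area(mesh)
        want = truth.total_leaf_area + truth.stem_area
        assert got == pytest.approx(want, rel=1e-6)

    def test_calibration_scales_linearly(self, unit_cube_mesh):
        full = estimate_leaf_area(unit_cube_mesh, calibration=1.0)
        assert estimate_leaf_area(unit_cube_mesh, calibration=0.5) == pytest.approx(full / 2)

    def test_empty_mesh_gives_zero(self):
        empty = TriangleMesh(vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=int))
        assert estimate_leaf_area(empty) == 0.0

    def test_lai_simple_ratio(self, unit_cube_mesh):
        # 6 cm² over 1 m²: LAI = 6e-4; doubling the ground halves it
        assert estimate_lai(unit_cube_mesh, 1.0) == pytest.approx(6e-4)
        assert estimate_lai(unit_cube_mesh, 2.0) == pytest.approx(3e-4)

    def test_lai_rejects_nonpositive_area(self, unit_cube_mesh):
        with pytest.raises(ValueError):
            estimate_lai(unit_cube_mesh, 0.0)

    def test_canopy_lai_matches_ground_truth(self):
        mesh, truth = generate_canopy(n_plants=6, seed=9)
        got = estimate_lai(mesh, truth.cultivation_area)
        # whole-mesh LAI includes the stems; subtract their known area
        stem_lai = (truth.stem_area * 1e-4) / truth.cultivation_area
        assert got - stem_lai == pytest.approx(truth.lai, rel=1e-6)

    def test_stacked_canopies_scale_lai(self):
        mesh, truth = generate_canopy(n_plants=4, seed=2)
        stacked = concatenate_meshes(
            [
                mesh,
                TriangleMesh(
                    vertices=mesh.vertices + [0, 0, 500], triangles=mesh.triangles
                ),
            ]
        )
        one = estimate_lai(mesh, truth.cultivation_area)
        two = estimate_lai(stacked, truth.cultivation_area)
        assert two == pytest.approx(2 * one, rel=1e-9)


class TestPlantHeight:
    def test_extent_from_vertices(self):
        mesh = TriangleMesh(
            vertices=[[0, 0, 5], [1, 0, 5], [0, 1, 155]],
            triangles=[[0, 1, 2]],
        )
        assert estimate_plant_height(mesh) == pytest.approx(150.0)

    def test_invariant_under_xy_rotation_and_z_translation(self, rng):
        mesh, _ = generate_plant(height=120.0, seed=3)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = TriangleMesh(
            vertices=mesh.vertices @ R.T + [40, -20, 17], triangles=mesh.triangles
        )
        assert estimate_plant_height(moved) == pytest.approx(
            estimate_plant_height(mesh), abs=1e-9
        )

    @pytest.mark.parametrize("h", [60.0, 120.0, 180.0])
    def test_generator_heights_recovered(self, h):
        mesh, _ = generate_plant(height=h, seed=int(h))
        assert estimate_plant_height(mesh) == pytest.approx(h, abs=0.1)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError):
            estimate_plant_height(np.zeros((0, 3)))

    def test_base_percentile_discounts_floor_noise(self):
        pts = np.zeros((101, 3))
        pts[:, 2] = np.concatenate([[-50.0], np.linspace(0, 100, 100)])
        assert estimate_plant_height(pts) == pytest.approx(150.0)
        assert estimate_plant_height(pts, base_percentile=2.0) == pytest.approx(
            100.0, abs=2.0
        )


class TestCanopyStructure:
    def test_point_mass_fills_one_bin(self):
        mesh = TriangleMesh(
            vertices=[[0, 0, 5], [1, 0, 5], [0, 1, 5]], triangles=[[0, 1, 2]]
        )
        profile = canopy_structure(mesh, bin_height=10.0)
        assert len(profile.bin_areas) == 1
        assert profile.bin_areas[0] == pytest.approx(0.5)

    def test_conservation_of_total_area(self):
        for seed in range(5):
            mesh, _ = generate_canopy(n_plants=3, seed=seed)
            profile = canopy_structure(mesh, bin_height=10.0)
            assert profile.total_area == pytest.approx(
                total_surface_area(mesh), rel=1e-12
            )

    def test_uniform_leaf_placement_gives_flat_profile(self):
        # identical leaves stacked at regular heights: every interior bin equal
        leaves = []
        for k in range(40):
            z = 2.5 + 5.0 * k
            leaves.append(
                TriangleMesh(
                    vertices=[[0, 0, z], [10, 0, z], [0, 10, z]],
                    triangles=[[0, 1, 2]],
                )
            )
        mesh = concatenate_meshes(leaves)
        profile = canopy_structure(mesh, bin_height=10.0)
        assert np.allclose(profile.bin_areas, profile.bin_areas[0])

    def test_empty_mesh_gives_empty_profile(self):
        empty = TriangleMesh(vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=int))
        profile = canopy_structure(empty)
        assert len(profile.bin_areas) == 0

    def test_bad_bin_height_rejected(self, unit_cube_mesh):
        with pytest.raises(ValueError):
            canopy_structure(unit_cube_mesh, bin_height=0)


class TestDryWeight:
    def test_noiseless_line_fits_exactly(self, rng):
        area = rng.uniform(100, 5000, size=20)
        w = 0.01 * area + 2.0
        model = fit_dry_weight_model(np.column_stack([area, w]))
        assert model.slope == pytest.approx(0.01, rel=1e-9)
        assert model.intercept == pytest.approx(2.0, rel=1e-6)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        area = rng.uniform(500, 8000, size=50)
        w = 0.012 * area + 3.0 + rng.normal(0, 5.0, size=50)
        model = fit_dry_weight_model(np.column_stack([area, w]))
        assert model.slope == pytest.approx(0.012, rel=0.10)

    def test_through_origin_variant(self, rng):
        area = rng.uniform(100, 5000, size=30)
        model = fit_dry_weight_model(
            np.column_stack([area, 0.008 * area]), through_origin=True
        )
        assert model.intercept == 0.0
        assert model.slope == pytest.approx(0.008, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_dry_weight_model([[100, 1], [200, 2]])  # n < 3
        with pytest.raises(ValueError, match="variance"):
            fit_dry_weight_model([[100, 1], [100, 2], [100, 3]])

    def test_predict_arithmetic_and_floor(self):
        from canopyscan.growth import DryWeightModel

        model = DryWeightModel(
            slope=0.01, intercept=2.0, target="total", species="tomato", r_squared=1.0
        )
        assert predict_dry_weight(model, 1000.0) == pytest.approx(12.0)
        neg = DryWeightModel(
            slope=0.01, intercept=-1.0, target="total", species="t", r_squared=1.0
        )
        assert predict_dry_weight(neg, 0.0) == 0.0

    def test_fit_predict_round_trip(self, rng):
        area = rng.uniform(100, 5000, size=10)
        w = 0.02 * area + 1.5
        model = fit_dry_weight_model(np.column_stack([area, w]))
        for a, truth in zip(area, w):
            assert predict_dry_weight(model, a) == pytest.approx(truth, rel=1e-9)
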