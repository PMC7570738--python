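# canopyscan

Non-destructive growth and yield monitoring of greenhouse fruit vegetables
(tomato, cucumber, paprika) from handheld 3D-scanner output. Growth surveys
of tall fruit vegetables are traditionally destructive — cut the plant, run
every leaf through an area meter, dry and weigh it. A 3D scan of the plant
or canopy replaces that: this package turns the scanner's two products, a
colored point cloud (PTS) and a triangulated surface model (STL), into leaf
area, leaf area index (LAI), plant height, vertical canopy structure, dry
weight, and fruit fresh weight.

## What it computes

**Leaf area** integrates the polygon areas of a trimmed plant surface model.
For a triangle with corners O, A, B and edge vectors a⃗ = A−O, b⃗ = B−O,

    area(ΔOAB) = ½ √[(a₂b₃−a₃b₂)² + (a₃b₁−a₁b₃)² + (a₁b₂−a₂b₁)²]

summed over all polygons. The allometric route, `area = a · length · width`
with species coefficients a (tomato 0.25, cucumber 0.87, paprika 0.59), is
also provided, along with a through-origin fitter that recovers `a` from
(length × width, area) pairs.

**LAI** = canopy leaf area (m²) / cultivation ground area (m²).
**Plant height** = z extent of the model, base to growing point (z-up).
**Canopy structure** = leaf area per height bin (default 10 cm).
**Dry weight** = a linear regression on leaf area, fit per species.

**Fruit weight**: mature fruits are extracted from a colored canopy cloud by
strict RGB gates (tomato R>140, G<100, B<100; paprika R>150, G>110, B<50),
grouped into per-fruit instances by Euclidean clustering, voxelised with
interior flood-fill to form a solid, and weighed as

    W (g) = V (cm³) × ρ (g·cm⁻³),   ρ_tomato = 0.84, ρ_paprika = 0.59.

**Evaluation**: every estimator is validated by regressing estimated on
measured values, reporting slope, intercept, R², and the RMSE of the raw
pairs.

Because no public scan archive accompanies the method, the `synthetic`
module generates plants (planar elliptical leaves whose true areas are
exact shoelace areas), six-plant zigzag canopies (33 cm spacing), and
fruit-bearing clouds with known fruit volumes — so every estimate can be
checked against analytic ground truth.

## Worked example

```sh
canopyscan simulate --kind plant --species tomato --seed 3 --height 120 --out-prefix demo/plant
canopyscan growth plant demo/plant.stl --out demo/report.json
```

prints

```
leaf_area_cm2=4905.38 plant_height_cm=120.00
```

— the integrated polygon area of the model (4464.5 cm² of true leaf plus
440.9 cm² of stem surface; the ground-truth CSV written next to the STL
itemises the per-leaf areas) and the base-to-growing-point height, which
matches the generated 120 cm exactly. For yield:

```sh
canopyscan simulate --kind fruits --species tomato --seed 5 --out-prefix demo/scene
canopyscan yield demo/scene.pts --species tomato --unit cm --out demo/yield.csv
```

prints

```
fruits=5 total_weight_g=654.04
```

five detected fruit clusters and their summed weight; the per-fruit CSV
holds point counts, voxel volumes, and weights plus a TOTAL row. Against
the scene's analytic truth (ρ·Σ 4/3 π r³ = 644.05 g) the estimate is
within 1.6 %. Every command writes a `*.provenance.json` sidecar echoing
the configuration and input checksums.

The same workflows are available as library calls (`canopyscan.estimate_leaf_area`,
`canopyscan.canopy_yield`, ...) on in-memory meshes and clouds.

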