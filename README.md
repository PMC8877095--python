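# bowlrecon

Single-image 3D reconstruction of round dining bowls, and food/liquid volume
estimation from later meal images.

A paper ruler (adhesive tape printed with equally spaced markers) is taped
centrally across the bottom and sides of a bowl and photographed from above.
The observed distortions of the tape width and marker spacing encode the
bowl's shape: `bowlrecon` recovers per-marker ray lengths by constrained
nonlinear least squares (law-of-cosines chord residuals with flat-bottom
equality constraints), symmetrizes the resulting cross-section, and revolves
it into a bowl-of-revolution model with diameter, depth, capacity, and a
level-to-volume table.

Given a reconstructed bowl and a meal image, the package locates the bowl
from its elliptical rim (circle pose from a known diameter), projects
volume-increment levels into the image, and estimates liquid/food volume
either by matching a flat liquid surface to the nearest projected level or
by a regression of volume on the food-area ratio (visible liquid area over
within-rim area). Results are reported as absolute volume and as bowl
"fullness" (percent of capacity).

A forward simulator generates everything the pipeline consumes — parametric
bowls (cylinder / spherical-cap / power-wall / cone-frustum, optional
rounded interior junction), projected ruler annotations with pixel noise,
and simulated fills — with exact ground truth, so all tests run without
external data.

## Command line

```sh
# generate a synthetic scene (annotation CSV/YAML, intrinsics, fill fixtures)
bowlrecon simulate --family spherical-cap --rb 35 --rr 62 --depth 50 \
    --noise-px 0.5 --seed 7 --out-dir sim/

# reconstruct the bowl model from a ruler annotation
bowlrecon reconstruct --annotation sim/annotation.csv --meta sim/annotation.yaml \
    --intrinsics sim/intrinsics.yaml --out bowl.json [--mesh bowl.obj]

# estimate liquid volume from a meal image annotation
bowlrecon estimate-volume --bowl bowl.json --intrinsics sim/intrinsics.yaml \
    --rim sim/rim.csv --surface sim/surface.csv --increment-ml 50 --out result.json
# ... or from segmentation pixel counts (area-ratio regression)
bowlrecon estimate-volume --bowl bowl.json --intrinsics sim/intrinsics.yaml \
    --rim sim/rim.csv --far-liquid 250000 --far-rim 1000000 --out result.json

# per-bowl relative-error table (defaults to the built-in nine-bowl benchmark)
bowlrecon report [--measurements rows.csv] [--out report.csv]
```

Annotation formats are plain text: landmark CSV (`index, border, x_px, y_px`,
top-left-origin pixels) with a YAML sidecar (ruler width, marker spacing or
per-interval spacings, flat-bottom index range, image dimensions); rim and
surface point CSVs (`x_px, y_px`); bowl models as JSON profiles.

## Layout

- `bowlrecon.camera` — pinhole conventions, pixel/image-plane conversion
- `bowlrecon.annotations` — annotation and bowl-model I/O
- `bowlrecon.reconstruction` — border fitting, ray optimization,
  symmetrization, revolution
- `bowlrecon.pose` — ellipse fitting, circle pose, levels, surface matching,
  area-ratio regression, fullness
- `bowlrecon.simulate` — parametric bowls and the forward simulator
- `bowlrecon.report` / `bowlrecon.benchmarks` — error tables and the
  nine-bowl reference data
- `bowlrecon.cli` — the `bowlrecon` entry point
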