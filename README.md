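# afmsim

Headless simulated AFM scanning of biomolecular structures.  `afmsim` turns
PDB files (single structures or multi-MODEL trajectories) into tip-convolved
AFM height maps using a hard-collision tip model — a probe sphere of radius
*R* capped by a tangent cone of half-angle *α* — scanned over a square grid
of step *a*.  It also provides Gaussian-blur post-processing, bilinear
resampling, AFM-style rendering, simulated AFM movie export, and a Pearson
image-correlation score for comparing simulated maps against experimental
AFM rasters.

## How it works

1. **Parse** — ATOM/HETATM records are read from fixed-column PDB text, one
   frame per MODEL block.  Coordinates are converted to nm and each atom gets
   a Van der Waals radius from a Bondi-style element table (overridable; an
   optional default radius covers unlisted elements).
2. **Orient & stage** — the structure is rotated about its centroid
   (intrinsic Z-Y-Z Euler angles or an explicit rotation matrix) and dropped
   onto the virtual stage plane *z = 0* so its lowest VdW sphere touches the
   plane.
3. **Scan** — for each grid cell the tip is lowered along the cell axis until
   it first touches any atom's VdW sphere.  The contact height has a
   two-branch closed form (probe-sphere contact for small lateral offsets,
   cone-flank contact beyond the tangency distance); the cell value is the
   maximum over atoms, clamped at 0.  The closed form is validated in the
   test suite against an independent brute-force tip-lowering oracle.
4. **Post-process / compare** — optional Gaussian blur (σ in nm, 4σ
   truncation, reflect boundaries), background cleaning by a max-fraction
   threshold, and a Pearson correlation score *C* over a region of interest
   (affine-invariant in intensities; cosine similarity available as an
   alternative).

Heights are exported as a plain-text tab-separated matrix with `#` header
lines carrying the full grid geometry, tip parameters and run configuration;
the text format round-trips bit-exactly.

## CLI

```sh
# synthetic test structures (single_atom, dimer, chain, helix, ring)
afmsim fixture ring -o ring.pdb --n 7 --ring-radius 2.0 --frames 5

# scan a structure: height-map text matrix + rendered PNG
afmsim scan ring.pdb --out-map map.txt --out-image map.png \
    --tip-radius 1.0 --alpha 10 --step 0.5 --rotation 0,90,0

# scan a multi-MODEL trajectory into a PNG sequence + animated GIF
afmsim movie ring.pdb -o movie_out --fps 5

# correlation score between two rasters (text matrix or PNG/TIFF)
afmsim compare map.txt experiment.png --pixel-size 0.5 --roi 10:50,10:50
```

Angles are degrees at the CLI (radians internally).  Defaults: *R* = 1.0 nm,
*α* = 10°, *a* = 0.5 nm, margin 2 nm, blur off.  Any flag can be seeded from
a `key=value` config file via `--config`; explicit flags win.  `compare`
prints *C* with 3 decimals and exits with status 2 when the correlation is
undefined (zero variance in the ROI).

## Library

```python
from afmsim import (FixtureSpec, make_fixture, TipModel, Orientation,
                    orient, stage, build_grid, scan)

ring = make_fixture(FixtureSpec(kind="ring", n=7, ring_radius=2.0))[0]
staged = stage(orient(ring, Orientation.from_euler_zyz(0, 90, 0)))
tip = TipModel.from_degrees(radius=1.0, half_angle_deg=10.0)
hmap = scan(staged, tip, build_grid(staged, step=0.5, margin=2.0))
```

## Scope notes

The scanning model is an idealization: non-elastic hard contact with rigid
VdW spheres, an infinite cone flank, no elastic deformation, no noise model,
and no attempt to reproduce experimental absolute height scales.  Interactive
viewing, experimental data acquisition, flexible fitting and automated
orientation search are out of scope.
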