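# tissuetracks

Time-continuous reconstruction of 2D gene expression patterns on a growing
triangulated tissue domain, from sparse, staged static snapshots.

## The problem

For embryos that develop internally (e.g. mouse), time-lapse imaging of gene
expression beyond early stages is not feasible: each specimen yields a single
static snapshot (a whole-mount in situ hybridization or HCR image), staged to
a developmental age after the fact. Understanding patterning dynamics — say,
how *Sox9* expression resolves into the skeletal pattern of the limb bud —
requires stitching many such snapshots from different individuals into one
smooth movie of expression over the growing tissue.

The difficulty is that gene expression patterns do not respect anatomical
coordinates: tissue flows and grows while patterns shift through it.
`tissuetracks` solves this by turning the spatial interpolation problem into
many small temporal ones:

1. **Morphomovie** — the growing tissue is represented as a sequence of 2D
   triangle meshes, one per developmental hour, with fine (10-min) vertex
   displacement substeps and hourly remeshing at constant element size.
2. **Lineage DAG** — since remeshing destroys triangle identity, triangles of
   consecutive hours are linked by *area overlap* in their common domain
   instant, forming a weighted directed acyclic graph.
3. **Tissue tracks** — from each final-hour triangle, walk the DAG backwards,
   always choosing the predecessor with maximal overlap; triangles missed by
   this pass seed additional tracks completed both backwards and forwards.
   Every triangle of every hour ends up in at least one full-span track.
4. **Digitization** — each staged image, registered to its hour's mesh by an
   affine transform, is reduced to one intensity per triangle (internally
   1 = high expression; chromogenic dark-signal stains are inverted on entry).
5. **Temporal B-spline** — expression along each track is a scatter of
   (hour, intensity) samples; their per-hour means become the control points
   of a uniform cubic B-spline curve, giving a C² trajectory with local
   control. Mapping every track's curve back onto the meshes (averaging
   triangles shared by several tracks) yields a full reconstruction at every
   hour — including hours with no image at all.
6. **Bootstrap** — raw images carry inconsistent intensity scales; each raw
   field is histogram-matched against the first-pass reconstruction of its
   hour, and the reconstruction is rebuilt from the matched fields.
7. **Evaluation** — reconstructions are scored against reference fields by
   the sum of squared differences after fitting a piecewise-linear intensity
   transform `g(D; x, y, D_min, D_max)` with `(x, y)` optimized over
   `[0, 1]²`, so pattern shape is compared rather than stain strength.
   A subset experiment quantifies how many input images a pattern of given
   complexity needs.

A synthetic-data module generates growing limb-bud-like morphomovies, smooth
dynamic ground-truth patterns (a sweeping expression front and a branching
stripe pattern), and corrupted staged images, so the whole pipeline is
testable end to end without laboratory data.

## Worked example

```python
import numpy as np
from tissuetracks import (GrowthSpec, PatternSpec, synthesize_dataset,
                          reconstruct, coverage_report)

growth = GrowthSpec(T=12, seed=1)                     # 12-hour growing domain
pattern = PatternSpec(kind="complex_stripes", duration_hours=12)
ds = synthesize_dataset(growth, pattern)              # movie + images + truth

report = coverage_report(ds.tracks, ds.movie)
print(f"tracks: {report['total_tracks']} "
      f"({report['fill_tracks']} fill), coverage complete: {report['fully_covered']}")

rec = reconstruct(ds.movie, ds.tracks, ds.fields)
mae = np.mean([np.abs(rec.fields[h].values - t.values).mean()
               for h, t in enumerate(ds.truth)])
print(f"reconstruction MAE vs ground truth: {mae:.4f}")
```

prints

```
tracks: 544 (222 fill), coverage complete: True
reconstruction MAE vs ground truth: 0.0099
```

544 tissue tracks cover the 12 hourly meshes (one per final-hour triangle
plus 222 fill tracks for intermediate triangles the backward pass missed);
reconstructing from one noiseless image per hour recovers the ground-truth
branching-stripe pattern to about 0.01 mean absolute intensity error on the
[0, 1] scale.

The same pipeline is available from the shell:

```sh
tissuetracks simulate --out data/ --seed 1 --pattern complex_stripes
tissuetracks run --config config.json --out rundir/
tissuetracks --help          # simulate, lineage, track, digitize,
                             # reconstruct, bootstrap, evaluate,
                             # subset-experiment, run
```

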