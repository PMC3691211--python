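# mtquant

Quantification toolkit for microtubule (MT) network architecture,
dynamics and in vitro assays, aimed at cell biologists analysing MT
repolymerization and non-centrosomal nucleation experiments (e.g.
nocodazole-washout assays, EB1 comet imaging, in vitro nucleation and
immunogold EM).

Most mammalian cells nucleate MTs at the centrosome, producing a radial
"aster"; regulators such as small heat-shock proteins can shift the
balance toward non-centrosomal MT formation.  Measuring that shift
requires a set of image- and track-level statistics that this package
implements as tested, scriptable building blocks, together with
synthetic ground-truth generators that make every stage verifiable.

## What it computes

**Microtubule Distribution Index (MDI).**  From a central point inside
the cell, `n = ⌊360°/Δθ⌋` straight line profiles are cast to the cell
border (120 lines at the default Δθ = 3°).  For line *j*, let `I_i` be
the mean intensity over the inner 10% of the line (near the center) and
`I_o` the mean over the outer 40% (near the periphery).  The per-line
ratio is `R_j = I_o / I_i` and

```
MDI = (1/n) Σ_j R_j
```

A low MDI indicates a centrosome-concentrated (aster-like) network; a
high MDI a dispersed one.  Lines with zero inner intensity are excluded
as undefined.

**Filament counting.**  A Hessian ridge (tubularity) filter at a chosen
scale enhances curvilinear structures and suppresses blobs such as the
centrosome core; the response is binarized (Otsu by default), thinned to
1-pixel skeletons, and 8-connected components are counted.  Path length
sums skeleton steps (diagonals weighted √2).  A per-image upper size
bound removes overlapping MTs merged into one object; a second
(acetyl-tubulin) channel flags pre-existing MTs so that only objects
with no acetylation signal are counted as *de novo* formed.

**Dynamic instability.**  Tip tracks are segmented per frame pair: a
displacement below 0.3 µm/frame is pause; larger displacements are
growth or shrinkage by the sign of their projection away from a
reference point.  Catastrophe frequency = transitions from growth (or
pause) into shrinkage per minute of growth+pause time; rescue frequency
= transitions from shrinkage (or pause) into growth per minute of
shrinkage+pause time.  Phase time percentages sum to 100 exactly.

**Comet origin.**  EB1-like comet tracks followed for more than three
frames are classified as centrosomal (start within a radius of the
centrosome and moving outward) or non-centrosomal (start beyond an
ambiguity band); everything else is excluded as ambiguous.

**In vitro assays.**  Nucleation fields: fixed-minimum intensity
threshold, connected-component particle count and size, aggregated as
mean ± SEM over ≥25 fields.  Immuno-EM: gold particles per µm of MT and
the Spearman rank correlation between per-MT density and length (exact
permutation p-value for n ≤ 10).

## Worked example

```python
import numpy as np
import mtquant as mq
from mtquant.synthetic import ImageSpec, make_filament_image
from mtquant.filaments import enhance_tubular, skeletonize_and_count
from mtquant.mdi import compute_mdi

spec = ImageSpec(width_px=256, height_px=256, psf_sigma_px=1.0,
                 background_level=0.05, seed=1)
ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
cell = mq.CellGeometry((128, 128), np.column_stack(
    [128 + 110 * np.cos(ang), 128 + 110 * np.sin(ang)]))

aster, _ = make_filament_image(spec, 60, (3.0, 8.0), layout="aster",
                               centrosome_px=(128, 128), region=cell)
dispersed, _ = make_filament_image(spec, 60, (3.0, 8.0),
                                   layout="dispersed", region=cell)
print(f"aster MDI      = {compute_mdi(aster, cell).mdi:.3f}")
print(f"dispersed MDI  = {compute_mdi(dispersed, cell).mdi:.3f}")

img, truth = make_filament_image(
    ImageSpec(width_px=256, height_px=256, psf_sigma_px=1.0, seed=1),
    20, (2.0, 5.0), min_separation_px=6.0)
fset = skeletonize_and_count(enhance_tubular(img, scale_px=1.0))
print(f"filaments: {fset.n_objects} objects, "
      f"total {fset.total_length_um:.1f} um (truth {truth.total_length_um:.1f} um)")
```

prints

```
aster MDI      = 0.077
dispersed MDI  = 0.728
filaments: 20 objects, total 70.0 um (truth 67.9 um)
```

The aster image — identical filament lengths, all emanating from the
centrosome — scores an order of magnitude lower MDI than the dispersed
image, and the skeleton pipeline recovers the exact filament count with
a total-length error of ~3%.

## Command line

```sh
mtquant simulate --out-dir sim --n-filaments 20 --min-separation 6 --seed 3
mtquant filaments --image sim/image.tif --out objects.csv
mtquant mdi --image cell.tif --roi roi.csv --angle 3 --inner 0.10 --outer 0.40 --out mdi.csv
mtquant dynamics --tracks tracks.csv --static-thresh 0.3 --frame-interval 3 --ref -1000,100 --out dyn.csv
mtquant comets --tracks comets.csv --centrosome 150,150 --out origins.csv
mtquant nucleation --images field1.tif --images field2.tif --min-intensity 20 --out fields.csv
mtquant emdensity --polylines poly.csv --particles part.csv --out em.csv
```

Every output CSV starts with a commented metadata header (package
version, config hash, and the verbatim parameters of the run).

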