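# mechanoquant

Quantification of the mechanical readouts of collective tumor-organoid
invasion in fibrillar collagen: per-cell Yap nuclear/cytoplasmic ratios,
the nematic order parameter of collagen-fiber alignment at the organoid
rim, the protrusive index of tumor borders, and drift-corrected
displacement of matrix-embedded beads. It is aimed at groups analyzing
multichannel confocal images (DAPI / K8 / K14 / Yap / collagen reflection)
and time-lapse bead movies of organoids cultured in Collagen I.

Every analysis stage has a matching synthetic-data generator with exact
ground truth, so the whole pipeline is testable without any experimental
images.

## The quantities

**Yap nuclear/cytoplasmic ratio.** After organoid segmentation (Otsu on the
combined K8+K14 signal), nucleus detection (k-means intensity classes on
DAPI plus seeded watershed splitting), and cell segmentation (watershed on
a multi-scale Hessian ridge elevation), each cell's ratio is

    r = (⟨I_Yap⟩_nucleus − b) / (⟨I_Yap⟩_cytoplasm − b)

with background `b` estimated as the median intensity outside the dilated
organoid mask. Cells are classified outer/inner by contact with the
organoid boundary, K14 Hi/Lo against the mean K14 level of outer cells,
and rim/leader by elongation and protrusion beyond the organoid's convex
body outline.

**Nematic order parameter.** Per-pixel fiber orientation θ ∈ [−90°, 90°)
and coherency come from the structure tensor. The alignment of an
orientation sample is summarized by the second-order tensor

    Q = [[⟨cos 2θ⟩, ⟨sin 2θ⟩], [⟨sin 2θ⟩, −⟨cos 2θ⟩]],
    λ₁,₂ = ±S,   S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²)

S = 0 for uniformly distributed axial angles and S = 1 for perfect
alignment. S is measured in 30 × 50 µm rectangles anchored on the organoid
boundary with the long axis along the outward normal (distance zero at the
cell–matrix interface), within 50 µm of the rim.

**Protrusive index.** Gaussian blur → threshold → erosion → largest
component; the index is the subpixel boundary perimeter divided by the
perimeter of its convex hull (1 for convex borders).

**Bead displacement.** Stage drift is removed by subpixel phase
correlation; beads are detected by bandpass peak detection and linked by
mutual nearest neighbors. A bead is included if its track is complete,
it starts within one organoid diameter (or radius) of the border, and it
is not within the selection distance of two organoids at once. The
displacement toward the organoid is the initial minus final distance to
the border, in µm.

## Worked example

```python
import numpy as np
import mechanoquant as mq

# a synthetic organoid: 16 rim cells at true Yap ratio 2.0, inner cells 1.0
spec = mq.SyntheticOrganoidSpec(seed=1, noise_sd=2.0)
img, truth = mq.gen_organoid_image(spec)

org = mq.segment_organoid(img)[0]
nuclei = mq.detect_nuclei(img["DAPI"], org)
cells = mq.segment_cells(nuclei, img, org)
records = mq.quantify_cells(img, cells, org)

rim = [r.nuc_cyto_ratio for r in records if r.role == "rim" and r.valid]
inner = [r.nuc_cyto_ratio for r in records if r.layer == "inner" and r.valid]
print(len(records), sum(1 for r in records if r.layer == "outer"))
print(round(np.median(rim), 3), round(np.median(inner), 3))
```

prints

```
35 16
1.833 0.999
```

— all 35 cells are segmented, the 16 rim cells are all classified outer,
and the median ratios recover the rim/inner contrast (true values 2.0 and
1.0; the rim median sits slightly low because watershed boundaries mix a
few cytoplasm pixels between neighbors). The order-parameter API works on
plain angle lists, e.g. `mq.order_parameter([0.0, 45.0]).S` →
`0.7071067811865476` (= √½, since ⟨cos 2θ⟩ = ⟨sin 2θ⟩ = ½).

A CLI mirrors the library: `mechanoquant synth|segment|yap|fibers|morph|beads|run`
(see `mechanoquant --help`).

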