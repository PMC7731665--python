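# cytozone

Per-cell subcellular segmentation and antibody-distribution quantification
for multichannel immunofluorescence imaging.

## The problem

Autoantibodies differ not only in *what* they bind but in *where* in the
cell they bind it. Given a field of view (FOV) acquired as separate stain
channels — a nuclear dye (Hoechst), a cytoskeleton marker (anti-vimentin
V9), a diffuse cytoplasmic marker (anti-ENO1), and a test antibody —
`cytozone` segments every cell, partitions it into named subcellular
zones, and quantifies how the test antibody's signal distributes across
them. It is aimed at groups characterising monoclonal antibody reactivity
on cultured cell monolayers (e.g. HEp-2) or, in FOV-level "tissue mode",
on stained tissue sections.

## Method

1. **Preprocessing.** Each structural channel is reduced to a binary mask
   with a classical 256-bin histogram autothreshold — Otsu
   (between-class-variance maximisation) for the nuclear channel, Tsai
   moment preservation ("Moments") for the cytoskeleton channel, and the
   Doyle percentile method for the cytoplasm channel — followed by one
   round of despeckling and hole filling.
2. **Marker composites.** Nuclei are labelled as 8-connected components.
   For each nucleus a *composite marker image* is built: that nucleus
   marked green, all others red, plus the binarized structure channel.
   This reduces instance segmentation to a semantic question: which
   structure pixels belong to *the* green nucleus.
3. **Per-cell assignment.** Two interchangeable backends answer it: a
   training-free *classical* backend assigning each structure pixel to
   its geodesically nearest nucleus, and a *trained* per-pixel 5-class
   softmax classifier (classes: target subcellular, target nucleus,
   other subcellular, other nuclei, background) optimised by SGD with
   momentum 0.9, learning rate 1e-3 dropping ×0.3 every 690 iterations
   (2300 total), inverse-pixel-frequency class weights and
   rotation/scale/reflection augmentation.
4. **Whole cells and zones.** whole = hole-filled union of the nuclear,
   cytoskeleton and cytoplasm segmentations. Canonical zones per cell:
   `nuc`, `vim_hi` (high-cytoskeleton zone, allowed to cross the
   nucleus), `cytoplasm = whole ∖ nuc`, `vim_lo = cytoplasm ∖ vim_hi`,
   plus arbitrary user zones via a union/difference algebra
   (`"nuc ∖ vim_hi"`).
5. **Quantification.** Mean pixel intensity (MPI) and area per (cell,
   zone); MPI ratios between zones; Pearson colocalization between the
   antibody channel and structural channels at cell and FOV scope;
   Mann-Whitney / paired Wilcoxon comparisons with Benjamini-Hochberg
   q-values. Segmentations are scored with intersection-over-union (IOU)
   and Spearman rank correlation of cell areas.

A synthetic-scene generator (elliptical nuclei and cytoplasm, fibrillar
random-walk cytoskeleton, antibody channel planted as a known mixture
`w_vim·S_vim + w_nuc·S_nuc + w_cyto·S_cyto + noise`) provides exact
ground truth for every stage.

## Worked example

```python
import numpy as np
from cytozone import (SceneParams, generate_fov, segment_fov,
                      fov_structure_masks, derive_zones, build_quant_tables, iou)

fov, truth = generate_fov(SceneParams(seed=0))          # 256x256, 5 cells
masks = fov_structure_masks(fov)
cells = segment_fov(fov)                                # classical backend
zonesets = [derive_zones(c, masks["cytoskeleton"]) for c in cells]
quant, coloc = build_quant_tables(fov, zonesets)
print(quant[quant.cell_id == 1][["zone", "area_px", "mpi"]].to_string(index=False))
```

prints, for the first cell:

```
     zone  area_px          mpi
    whole     3658  7821.541006
      nuc      523 14037.390057
   vim_hi      612 19115.674837
cytoplasm     3135  6784.574801
   vim_lo     2732  5123.627379
```

The default scene plants a vimentin-dominant antibody
(`w_vim=0.85, w_nuc=0.15`), and the zone MPIs recover that preference:
the vim_hi zone is the brightest antibody compartment (19116 intensity
units vs 14037 in the nucleus and 5124 in the remaining cytoplasm). The
FOV-scope colocalization shows the same thing as a pixel statistic —
r = 0.87 between antibody and cytoskeleton channels versus r = 0.50
against the nuclear channel — and the segmentation itself scores a mean
whole-cell IOU of 0.92 against the generator's exact geometry.

The same pipeline is available from the shell:

```bash
cytozone simulate --seed 7 --out run/sim
cytozone segment  --fov run/sim/fov_channels.json --out run/seg
cytozone quantify --fov run/sim/fov_channels.json \
    --zone-expr "nuc_only=nuc - vim_hi" --out run/quant
```

Every subcommand writes a `run_manifest.json` (config hash, seed,
version) sufficient to reproduce its outputs byte-identically.

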