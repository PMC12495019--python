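# epifocal

Quantitative spatial analysis of whole-mount curved epithelia imaged by 3D
confocal microscopy.

Flat-mounted epithelial sheets — the motivating case is the lens capsule
with its attached epithelial monolayer, retrieved at cataract surgery — are
never optically flat: each z-slice of a confocal stack is in focus only over
part of the field. `epifocal` turns such stacks into per-cell, per-compartment
protein measurements in four stages:

1. **Focal correction.** The DAPI channel's Sobel-gradient magnitude is
   maximized along z at every pixel; a total-degree-5 bivariate polynomial
   z_f(x, y) is fitted to the argmax map by least squares weighted with the
   thresholded gradient (weights below 0.1·prc99 are zeroed), and every
   channel is linearly interpolated along z onto the fitted surface to give
   a single sharp image I_f(x, y) = I(x, y, z_f(x, y)).
2. **Compartmental segmentation.** Two marker-controlled watershed
   transforms: the first grows nuclei on the DAPI gradient from h-maxima
   seed markers (h = 0.1·prc99.9 of the contrast-flattened DAPI) against a
   sub-median extranuclear marker; the second separates cells on the summed
   protein-channel gradients, seeded by the nuclei, with a 2 px kill zone
   around nuclear borders and an automatic marker for acellular space
   derived from the distance transform. Output: per-cell nucleoplasm and
   cytoplasm labels and mean intensities.
3. **Wound-edge profiling.** Column-averaged intensity vs distance from the
   cut/border, in 5 µm bins, summarized by the interval fraction
   IF = ⟨P⟩₍₅–₃₀₎ / (⟨P⟩₍₅–₃₀₎ + ⟨P⟩₍₅₀–₈₀₎): 0.5 means equidistribution,
   above 0.5 means proximal accumulation. Destruction areas between two
   polylines are computed by the shoelace formula.
4. **Colocalization and statistics.** Pixelwise PCC/SRCC with tile-shuffle
   (8×8 px) randomization p-values; Costes cooccurrence thresholds found by
   walking a *percentile-pairing* curve until the correlation of the
   sub-threshold pixels reaches zero; Manders M1/M2; per-cell nuclear
   fractions nucfr = nuc/(nuc+cyt) and compartment-pairing correlations with
   orthogonal regressions; Shapiro-Wilk-gated t/Welch/Wilcoxon comparisons
   with Cohen's d, d′ and probability-of-superiority effect sizes.

A synthetic-phantom generator (`epifocal.phantom`) renders stacks with a
known focus surface, contact-inhibited nuclei, controllable inter-channel
correlation, nuclear exclusion, defocus blur and Poisson–Gaussian noise, so
every stage has a ground-truth oracle.

## Worked example

```python
from epifocal import phantom, focal, segment, coloc

truth = phantom.make_phantom_truth(n_cells=30, channel_corr=0.7, seed=1)
stack, _ = phantom.render_stack(truth, n_slices=21)   # SNR-10 phantom stack

infocus = focal.correct_stack(stack)                  # fit z_f, interpolate
labels, table = segment.segment_infocus(infocus)      # two watersheds
table = coloc.nuclear_fractions(table)

print("cells:", labels.cell_count)
r = coloc.correlation(table["a_cyt_mean"], table["b_cyt_mean"])
print("per-cell cytoplasmic PCC(A, B):", round(r, 3))
rep = coloc.pixel_coloc(infocus["protein_a"], infocus["protein_b"],
                        n_perm=199, seed=1)
print("pixelwise PCC:", round(rep["pcc"], 3), "p =", round(rep["p_pcc"], 4))
print("Manders M1, M2:", round(rep["m1"], 3), round(rep["m2"], 3))
```

prints

```
cells: 30
per-cell cytoplasmic PCC(A, B): 0.545
pixelwise PCC: 0.846 p = 0.005
Manders M1, M2: 0.957 0.956
```

All 30 phantom cells are recovered. The per-cell cytoplasmic correlation
(0.545) estimates the generator's target of 0.7 within its n = 30 sampling
error, while the *pixelwise* PCC is much higher (0.846) because both protein
channels share the same nuclear-exclusion geometry — exactly the
compartment-cooccurrence inflation that the compartmental analysis is
designed to separate from true co-variation. The tile-shuffle p-value
(1/200) confirms the spatial correlation is not a tiling artifact.

A CLI mirrors the library:

```bash
epifocal phantom --cells 30 --corr 0.7 --seed 1 --out ph/
epifocal focal ph/phantom_stack.tif --out infocus.tif
epifocal segment infocus.tif --out seg/
epifocal run-all --phantom-samples 3 --seed 1 --out out/
```

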