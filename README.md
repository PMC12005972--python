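# cyclehcr

Post-detection analysis for **split-barcode multicycle HCR imaging** —
multiplexed single-molecule RNA (and protein) imaging in thick tissue, where
each transcript species is identified by a combination of a fluorescence
channel and a left/right pair of 14-bp readout barcodes, read out over many
imaging cycles. This package covers everything *after* spot detection and
nucleus segmentation: codebook design, 3D spot-to-cell assignment, quality
control, cell and gene clustering, embryo-axis geometry, spatial gradient and
co-expression analysis, and nuclear protein quantification. A synthetic-data
generator with complete ground truth ties the stages together and makes every
claim testable.

It is written for computational biologists working with image-based spatial
transcriptomics (MERFISH/seqFISH-style pipelines) who need a tested, scripted
path from decoded spot tables and label volumes to biological summaries.

## The core ideas

**Barcode combinatorics.** With `n_L` left and `n_R` right readout probes per
channel, a channel encodes `n_L × n_R` targets (900 at 30 × 30) and `C`
channels encode `n_L × n_R × C` (2,700 at three channels). Targets are
scheduled one per channel per cycle, so a library of `N` targets needs
`⌈N / C⌉` cycles — 89 cycles for 254 genes plus 12 non-targeting control
barcodes, 40 cycles for a 120-gene panel.

**Conservative spot assignment.** Nucleus label masks are dilated by a small
Euclidean radius (default 1.0 µm, anisotropy-aware, ties to the nearest
pre-dilation voxel with deterministic tie-breaks) and each spot is assigned to
the label of its containing voxel. Non-targeting barcodes have no matching
probe, so their counts estimate the false-positive floor:
`fp_rate = max_control_total / n_cells` (200 spots over 11,029 cells ≈ 0.018
spots per cell).

**Spatial statistics.** Cell positions are re-expressed on embryo-intrinsic
axes — distal–proximal (distance along the midline), anterior–posterior
(signed angle vs. the posterior reference, so left/right = sign of the angle),
and radial. Per-cluster expression gradients are ordinary least squares of
min–max-scaled expression against the [0, 1]-scaled axis coordinate, so the
slope *k* is dimensionless; along a curved band midline, cells are binned into
9 equal-arc-length segments and genes are classified descending/ascending/flat
by the slope over the first 8 segment means at |k| ≥ 0.15. Co-expression is
pairwise Spearman correlation within clusters; protein levels are per-nucleus
mean intensities normalized to an inactive-chromatin reference (H3K27me3) and
compared across clusters with one-way ANOVA plus Bonferroni-adjusted pairwise
Welch tests.

## Worked example

```python
import cyclehcr as chc

# 1. design a codebook and simulate an embryo with ground truth
cfg = chc.default_embryo_config(seed=1)              # ~1,500 cells, 9 clusters
cb = chc.build_codebook(cfg.genes, cfg.n_controls, seed=1)
volume, spots, truth = chc.generate_embryo(cfg, cb)

# 2. assign spots to dilated nucleus masks and build the count matrix
dilated = chc.dilate_labels(volume, radius_um=1.0)
assignment = chc.assign_spots(spots, dilated)
cm = chc.build_count_matrix(assignment, spots, volume, cb)

# 3. QC, clustering
rate, _ = chc.estimate_false_positive_rate(cm)
active = sorted(chc.filter_active_genes(cm))
rows = [cm.genes.get_loc(g) for g in active]
norm, _ = chc.normalize_counts(cm.counts[rows])
result = chc.cluster_cells(norm, seed=1, embed=False)

print(f"{len(spots)} spots, {cm.n_cells} cells")
print(f"false-positive rate {rate:.4f} spots/cell, {len(active)} active genes")
print(f"{result.n_clusters} clusters, sizes {sorted(result.sizes.values())}")
```

Output:

```
138803 spots, 1500 cells
false-positive rate 0.0007 spots/cell, 50 active genes
9 clusters, sizes [70, 110, 110, 110, 120, 190, 210, 260, 320]
```

138,803 decoded spots over 1,500 nuclei give a control-barcode noise floor of
0.0007 spots per cell; 50 of 60 genes pass the activity filter (10 are silent
by construction), and graph clustering recovers the 9 generating fate-map
clusters at their exact generating sizes.

The same stages are available from the shell:

```bash
cyclehcr simulate embryo --seed 1 -o out/
cyclehcr assign --spots out/spots.csv --labels out/labels.tif \
    --codebook out/codebook.tsv --dilate-um 1.0 -o out/matrix
cyclehcr qc --matrix out/matrix --codebook out/codebook.tsv -o out/qc.json
cyclehcr cluster --matrix out/matrix --seed 1 -o out/clusters
```

## Documentation

`docs/methods.md` describes the generative model behind the synthetic data,
the numerical conventions (coordinate handling, scaling before regression,
tie-breaking), the default parameters and why they were chosen, and the known
limitations of the synthetic benchmark.
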