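# Methods

## Scope and data model

The package starts where image processing ends. Its inputs are the products
of an upstream imaging pipeline: decoded single-molecule spot tables
(physical x/y/z in µm, channel, cycle, target, intensity), 3D integer label
volumes of segmented nuclei (multi-page TIFF with a JSON voxel-size sidecar),
codebook files, and per-nucleus protein intensity tables. Stitching,
registration, segmentation, and spot detection are deliberately out of scope;
those steps are served well by existing tools, and their outputs are this
package's inputs.

One coordinate convention is used everywhere: volumes are indexed (z, y, x),
0-based; spot coordinates are micrometres; the voxel of a spot is
`floor(coordinate / voxel_size)` per axis. Spots exactly on a voxel boundary
therefore belong to the upper voxel's predecessor deterministically.

## Codebook model

A target's identity is the triple (channel, left readout index, right
readout index); amplification requires both matched readout probes, which is
what makes the address space multiplicative: `capacity = n_L × n_R ×
n_channels`. Channels are fixed to the three instrument lines {488, 561,
640}. Scheduling is channel-first: target *i* of an ordered list lands in
cycle `i // C + 1` on channel `i mod C`, so `n_cycles = ⌈N / C⌉` and the last
cycle may be partially filled.

`build_codebook` shuffles the full (channel, L, R) lattice once per seed and
allocates sequentially through per-channel queues, keeping channels balanced
so the schedule matches the ceiling formula. Non-targeting controls are
appended after targets and drawn preferentially from combinations whose
(L, R) pair is unused by any target and whose L and R half-sites are each
used by at most one targeting entry; how real control combinations relate to
targeting half-site usage is not established practice, so the half-site-
minimizing rule is this package's choice, and it degrades gracefully on
small lattices where no fresh pair exists.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream guarantee is checked.

**Geometry.** The embryo preset arranges ~1,500 nuclei on an egg-cylinder
scaffold (radius 85 µm, height 245 µm at unit scale): three interior columns
(C1–C3) in nested radial shells of the distal half, mirrored across the
midplane; a demarcation band (C4); an extraembryonic cap (C5); endoderm
shells enclosing the embryonic (C6) and extraembryonic (C7) domains; an
outer equatorial ring (C8); and a sparse outermost shell (C9). The
hippocampus preset places 450 nuclei in three layers along a quadratic
planar midline curve; each cell's normalized arc-length position is recorded
as ground truth. All radii and densities are schematic — chosen so the nine
regions are distinct and placeable, not to match any measured anatomy.

**Nuclei.** Axis-aligned ellipsoids with 3.0 µm nominal radius (a ~6 µm
nuclear diameter) and 10% per-axis jitter, placed by random sequential
addition with a hard minimum center distance (sum of max semi-axes plus a
1.2 µm gap), so masks never share a voxel. A region too dense to accept its
cells within a bounded retry budget raises a placement error rather than
silently overlapping.

**Counts.** Per-cell transcript counts are negative binomial (default size
5; `size = inf` gives Poisson) with mean

    mu = base_rate × exp(beta · t) × exp(Σ loading · z_cell)

where `t` is the normalized axis coordinate (height fraction for the embryo,
arc length for the band), `beta` a per-gene log-linear gradient, and `z_cell`
standard-normal latent factors shared across loaded genes — the mechanism
that produces co-expression without spatial structure. NB was chosen because
image-based single-cell counts are overdispersed ("salt and pepper"
heterogeneity) but no explicit count model is established for this assay.

**Spots.** Each nuclear transcript is placed uniformly inside its nucleus's
ellipsoid dilated by 0.2 µm — transcripts sit in and immediately around the
nucleus. The halo is kept below the default mask dilation (1.0 µm) minus the
half-voxel-diagonal rasterization error (~0.87 µm at 1 µm voxels), which is
what makes ≥99% true-cell assignment geometrically achievable. Background
false positives are homogeneous Poisson over the bounding volume (default
0.05 per cell) with uniformly random identity over all codebook entries;
they are the *only* source of non-targeting counts. Spot intensity is
log-normal (σ = 0.4) scaled by the per-channel amplification fold
(103.7 / 88.3 / 121.3 for 488 / 561 / 640).

Everything is drawn from a single `numpy` generator seeded from the config,
in a fixed order, so identical configs produce byte-identical outputs.

**What the generator does not emulate:** optics (PSF, depth-dependent
attenuation, channel bleed-through), segmentation errors, registration
drift, cytoplasmic transcript pools, or realistic embryo anatomy. Passing
tests demonstrate that the analysis recovers what the generative model
encodes; they are not evidence about biological datasets beyond that.

## Spot-to-cell assignment

Dilation is exact nearest-labeled-voxel assignment restricted to the radius:
integer voxel offsets within the (anisotropy-scaled) radius are enumerated,
grouped by exact distance, and swept in increasing order; a background voxel
takes the minimum label among its nearest tie group. This reproduces the
brute-force per-voxel search bit-for-bit (verified against it in tests),
never alters pre-dilation labels, and is monotone in the radius. The default
radius of 1.0 µm operationalizes "slightly dilated" masks; it is a
configurable parameter recorded in output metadata. Cells removed by QC keep
flagged columns instead of being dropped, so `matrix sum == assigned spots`
holds unconditionally.

## Quality control

The false-positive rate is the most conservative reading of the control
counts: the *maximum* non-targeting total divided by the number of cells.
The active-gene threshold defaults to that same maximum control total (the
data-driven noise ceiling), with 200 as the documented fallback; the
cell-exclusion threshold defaults to 10 counts over active genes. Both are
exposed parameters — the exact thresholds behind published gene/cell counts
are not recoverable and are not claimed. Detection-rate stability is a
per-cycle mean-spots-per-active-gene series with an OLS trend and a 95% CI;
"stable" means the CI covers zero (with a small numerical slack so an
exactly flat series qualifies).

## Clustering

Depth normalization scales each cell to the median total before `log1p`;
PCA to 30 components, a symmetrized 15-NN graph, and Leiden community
detection at resolution 1.0 with a mandatory seed are standard single-cell
defaults, all logged in the result. Cells in communities smaller than 20,
plus cells with negative silhouette in PCA space, are marked unallocated
(label 0) — an operationalization of "no clear cluster association", which
has no canonical definition. Gene clustering orders average-linkage
correlation-distance trees of per-gene min–max-scaled cluster means;
constant genes scale to 0 and are flagged. Embedding-space imputation is
k-NN averaging (self included, k = 15), a row-stochastic smoother whose
output stays within the input range.

## Axes and gradients

The midline is the first principal axis of anchor-cluster centroids,
oriented so a designated proximal anchor cluster projects positive; the
posterior reference direction is orthogonalized against the midline. dp is
the projection shifted so the distal-most cell sits at 0; ap is the signed
angle (degrees, posterior = 0, right-hand rule about the midline, range
(−180, 180]); radial is the perpendicular distance. Cells exactly on the
midline get ap = 0 and a flag. The transform is rigid-motion invariant up to
the fitted axis conventions, verified numerically to 1e-6.

Gradient slopes are computed on doubly normalized variables: expression
min–max scaled over the fitting window, coordinate scaled to [0, 1]. This
makes *k* dimensionless and comparable across genes, and makes a fixed
threshold like |k| ≥ 0.15 meaningful — but it changes threshold semantics
relative to slopes on raw counts, and published gene tallies under
unspecified scaling are therefore not comparable and not claimed. A
consequence worth stating plainly: for a gene with *no* spatial signal, the
min–max step normalizes segment means by their own noise range, so the
fitted slope has a standard deviation of roughly 0.3 regardless of
expression level — truly flat genes cannot be reliably held below
|k| = 0.15. Recovery guarantees are therefore stated for designated
strong-gradient genes; the segment tables report all classes.

Segment classification bins band cells into 9 equal-arc-length segments,
fits the first 8 (per the protocol of reserving the terminal segment), and
classifies at |k| ≥ 0.15. Empty segments are skipped; fits on fewer than 4
segments are flagged. Spearman co-expression uses average ranks; constant
genes yield masked zeros; matrices are made exactly symmetric with unit
diagonal.

## Protein quantification

Per-nucleus antigen levels are mean voxel intensities over *undilated*
masks, ratioed per cell against an inactive-chromatin reference antigen
(H3K27me3 by default) to cancel local staining imbalance; cells with missing
or non-positive reference are excluded with a flag. Cluster comparison is
one-way ANOVA followed by pairwise Welch t-tests against a reference
cluster, Bonferroni-multiplied by the number of comparisons and capped at 1.
Welch was chosen because the base test behind "Bonferroni tests" is
unspecified and unequal variances are the safe assumption; the choice is
recorded in the output. Significance codes follow the conventional ladder
(n.s. / * / ** / *** / ****). Whether intensities should be
background-subtracted before ratioing is an open question; the package
ratioes raw mask means.

## Problem sizes and numerical notes

Default test-scale runs use ~1,500 embryo cells × 60 genes and 450 band
cells × 30 genes; `default_embryo_config(scale=7.3)` approximates the
full-size 11,000-cell setting with geometry scaled by the cube root of cell
number. Distance ties in dilation are resolved at 1e-9 tolerance to the
smaller label; the stability CI uses Student-t critical values; Spearman
matrices are validated against the textbook rank formula at 1e-12.

## Known limitations

- The synthetic geometry is schematic; cluster shapes, densities, and
  gradients are not calibrated to measurements.
- Real-data figures (specific cluster counts on real embryos, published
  gene tallies, amplification measurements) depend on unreleased raw images
  and are outside what this package can or does reproduce.
- The egg-cylinder midline is a straight principal axis; curved midlines are
  supported only for the band geometry (quadratic curve, dense arc-length
  sampling).
- Flat-gene classification under min–max scaling is noise-limited, as
  described above.
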