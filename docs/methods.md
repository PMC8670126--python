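# Methods

## The measurement model

The package treats a stained whole tissue section as a set of multichannel
fields of view (FOVs): a DAPI nuclear counterstain, a cytokeratin (CK)
epithelial channel, and up to three target markers per staining round.
Marker expression is quantified compartment-wise rather than cell-wise: a
compartment is a binary pixel mask (tumor = binarized CK; nuclear =
binarized DAPI; stroma = nuclear minus tumor; marker compartments =
binarized target channels), and the score for a target in a compartment is
the compartment-averaged intensity

    QIF(t, C) = sum_{p in C} I_t(p) / |C|.

This average is undefined on an empty compartment and is reported as
missing, never as zero — a zero would be a claim of absent expression, not
of absent evidence.

Assumptions inherited from this design: channels within a FOV are
pre-aligned; intensities are additive in the signal (no spectral mixing);
compartment masks from different markers may overlap freely; the stromal
compartment contains only nucleated stroma, because it is defined by
subtraction from the DAPI mask (non-nucleated extracellular matrix is
invisible to it).

### Acquisition normalization

Raw scores are linear in exposure time and full-scale value, so they are
rescaled multiplicatively to reference settings, T_ref = 100 ms and
b_ref = 8 bits:

    norm = raw * (T_ref / T) * ((2^b_ref - 1) / (2^b - 1)).

Only this linear contract is guaranteed; both reference constants are
config keys. The identity holds at the reference settings, doubling the
exposure halves the normalized score, and a full-scale signal normalizes
equally at any supported bit depth (8, 12, 16).

### QC filter

A FOV is excluded when it is flagged as a staining artifact (an operator
input, modelled as an explicit flag) or when its tumor fraction —
tumor area / (nuclear ∪ tumor) area — is below 2 %. The denominator is a
design choice: the source convention names only "2 % tumor", so the tissue
support is defined as the union of the two tissue masks, and the rule is
applied per FOV (the FOV is the scoring unit) with a section dropped when
no FOV survives. Raising the threshold can only shrink the included set
(verified as a property test).

## Section-level analysis

Each (marker, compartment) in each section is summarised by the median
normalized score over QC-included FOVs (midpoint convention for even
counts; invariant to FOV order). Group comparisons:

- **Mann–Whitney U**, two-sided, on section medians. The exact null
  distribution is used for pooled n ≤ 16 without ties; otherwise the normal
  approximation with tie and continuity corrections. Two degenerate cases
  are pinned analytically: an all-constant pooled sample has p = 1, and a
  U statistic exactly at the null centre nm/2 has two-sided p = 1 (every
  relabelling is at least as extreme), where the corrected normal
  approximation would report slightly less.
- **Fisher's exact test** on the active/dormant × group 2×2 table.
- **Pearson's chi-squared** (no Yates correction) for cohort characteristic
  tables, with Fisher substituted on 2×2 tables containing an expected
  count below 5. Which test the source tables used per row is not stated;
  this dispatch reproduces both printed chi-squared p-values.
- α = 0.05, no multiplicity adjustment by default (mirroring field
  practice of reporting ~17 unadjusted marker tests); a Benjamini–Hochberg
  column is available via `bh_adjust=True`.

p values are displayed as: "<0.001" below 0.001; two significant figures
below 0.2; one significant figure at or above 0.2. Percentages in the
summary table use denominators that exclude unknown values, which are
listed as bare counts and excluded from the tests; percentages print one
decimal below 10 % and integers otherwise.

### T-cell activation

A section is "high" for Ki67 (or GzB) when its CD3-compartment score is at
or above the pooled cohort median — ties go high, for determinism, so 2n
distinct scores always yield exactly n high sections. The default combiner
labels a section **active** when either marker is high; an AND combiner is
available because the activation schema is described only graphically in
the source material and both readings are defensible. The cutoff is pooled
across both groups (stratified medians would remove exactly the group
difference being tested).

### Cell phenotyping

Nuclei are segmented from DAPI by Otsu thresholding plus
distance-transform watershed seeded at local maxima (min distance 3 px by
default); per-cell means are measured over the nucleus expanded by a 3-px
cytoplasm ring. Phenotype calls are explicit conjunctive gates (Treg =
CD4 ≥ g₁ ∧ FOXP3 ≥ g₂), with per-marker Otsu on the cell-mean distribution
as the default gate; a trainable classifier is deliberately out of scope,
so gates are always inspectable numbers. Tissue category (tumor vs stroma)
is the majority pixel overlap of the cell footprint, ties to stroma — the
conservative direction for claims about tumor-infiltrating cells. Treg
density is count / pixel area per category per FOV, section-aggregated as
the median. Basement-membrane-excluded aSMA is scored on stroma minus the
union of binarized CD34/COL4/VWF masks, removing vascular and glandular
smooth muscle from the myofibroblast signal.

## The synthetic cohort generator

The generator emulates the acquisition geometry, not the optics: cells are
nuclear disks (radius 4 px) with a 3-px cytoplasmic annulus on a 256×256
default raster ("×20-like" scale); tumor cells carry CK in the annulus;
nuclear antigens (FOXP3, Ki67) paint the disk, other markers the whole
footprint. Per-cell intensities are truncated normals per phenotype;
channels get Gaussian background noise and are quantised to the configured
bit depth. Centroids are rejection-sampled with a minimum separation of
2r + 3 px so rasterised nuclei stay disjoint (a configurable overlap mode
exists for exercising the watershed split). Default cohort conditions are
two groups of 49 and 51 sections with 40–200 FOVs each, uniform per
section.

Two levels of variation make the statistics realistic:

- **Within section:** Poisson cell counts per phenotype (expected counts
  from a default panel of eight populations spanning the marker hierarchy:
  tumor, CD4/CD8 T cells, Tregs, B cells, macrophages, myofibroblasts,
  endothelium) and the per-cell intensity spread.
- **Between sections:** a per-section, per-marker lognormal multiplier
  2^N(0, σ) with σ = 0.5 log2 units. Biological marker expression across
  tumors commonly spans an order of magnitude; σ = 0.5 gives a ~1.4×
  geometric SD and dominates the section-score variance once a section has
  a handful of FOVs.

Planted group effects are log2 shifts on group-b marker means (or
phenotype abundances). Because the between-section term dominates, an
effect of d standard deviations of the section-level score is planted as
`effect_log2 = d * σ` (`effect_for_sd_shift`); within-section sampling
noise adds under 1 % of variance at the simulation sizes used, so the
realised d is within a few percent of the target.

What the generator does **not** emulate: point-spread functions,
autofluorescence, spectral bleed-through, staining chemistry, tissue
architecture (cells are spatially uniform), or segmentation-hostile
morphology. Passing tests therefore demonstrate the correctness of the
measurement and inference machinery on images satisfying the stated
geometry — not robustness to real histology.

### Seeding

One master seed; per-FOV streams are derived by counter-based splitting
(`SeedSequence(seed, spawn_key=(crc32(section_id), crc32(fov_id)))`), and
per-section streams by `spawn_key=(1, section_index)`, so generation order
never changes any result and any single FOV can be regenerated
bit-identically in isolation. Each FOV splits its stream once more into a
cell stream and a noise stream, so ground truth is identical whether or
not pixels are rendered.

## Numerical and design choices

- **Thresholding:** Otsu between-class-variance maximisation, with manual
  overrides retained because operator-set thresholds are standard in AQUA
  workflows. skimage's Otsu value is an exclusive lower bound
  (foreground = strictly greater); manual thresholds are inclusive. Otsu
  always splits a histogram, so the automatic path additionally requires
  the foreground class mean to exceed 1.5× the background class mean;
  otherwise the channel is declared signal-free and the mask is empty.
  Constant rasters are signal-free by definition (warned).
- **Morphological cleanup:** hole filling on, minimum object size 20 px;
  both config keys.
- **Coordinates:** row-major, 0-based; areas are pixel counts.
- **Scores:** kept linear (no log transform); missing channels in a FOV
  drop that FOV from the affected medians only, with counts reported.
- **Simulation sizes:** the type-I experiment uses 400 replicates of
  20 + 20 sections × 6 FOVs; the power experiment uses the prescribed 50
  sections per group × 200 replicates at 6 FOVs. Both run on
  ground-truth intensities summarised exactly as the analysis summarises
  images (per-FOV mean → section median → Mann–Whitney), which is the
  generator-level oracle for the comparison machinery; the image path
  (render → mask → score) is validated separately by the mask-algebra,
  scoring-oracle, QC-recall and end-to-end pipeline tests.
- **Group labels:** internally `a`/`b`; display labels are config strings
  (planted effects always apply to group b).

## Known limitations

- The stromal compartment excludes non-nucleated ECM by construction.
- The exact normalization arithmetic of commercial AQUA software is
  unpublished; only the linear reference-rescaling contract above is
  guaranteed.
- Gates replace trainable tissue/cell classification; on real images the
  Otsu defaults will need operator review.
- The chi-squared/Fisher dispatch for summary tables is a reconstruction
  (see above), validated against the rows whose printed values are
  internally consistent.
- Headline between-group marker differences from any particular study are
  not reproducible from this package alone: the underlying images and
  per-section scores of such studies are not public, so the pipeline's
  claims are calibration (type-I error at nominal α), power against
  planted effects, and exact reproduction of published summary-table
  arithmetic.
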