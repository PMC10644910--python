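# Methods

This note documents the models and procedures implemented in
`ganglion3d`, the parameters that matter, the numerical conventions that
make runs bit-reproducible, and what the synthetic scenes do and do not
establish about real data.

## Segmentation backends

The pipeline consumes either a per-voxel foreground probability map
produced outside the package (a UNET-style pixel classifier's export)
or computes a classical global Otsu threshold on the raw target
channel.

**Otsu.** The threshold maximizes between-class variance on a 256-bin
histogram built over the full 3D stack's intensity range. Global — not
per-plane — because depth attenuation makes plane-wise thresholds drift
systematically shallower with depth; a per-plane variant exists for
exploration (`--otsu-per-plane`). Conventions fixed for
reproducibility: the returned threshold is the upper edge of the argmax
bin; the mask is strict `intensity > t`; a zero-variance stack yields an
all-background mask; plateaus of the criterion (exact ties across empty
bins between well-separated modes) resolve to the lowest qualifying
threshold, with a 1e-9 relative tolerance so the choice is independent
of summation order.

**Probability maps.** 8- and 16-bit TIFF exports are rescaled by their
dtype maximum to [0, 1]; float maps must already be in [0, 1]. The
binarization cutoff defaults to 0.5 and is inclusive (`≥`).

**Resampling convention.** When enabled, each plane is bilinearly
resampled to 512×512 (the prediction resolution of per-plane
classifiers), binarized there, and the *binary* mask is upsampled back
by nearest neighbor. Binarizing before upsampling avoids
interpolation-softened edges being re-thresholded inconsistently;
nearest neighbor guarantees no new label values. The order
(binarize-then-upsample) is a package choice among defensible
alternatives.

## Instance separation

Stage order: spherical erosion → 3D connected components → minimum-size
filter → watershed splitting of oversized objects.

- **Erosion** uses a discretized ball structuring element in voxel
  space (anisotropic spacing is deliberately ignored inside morphology;
  physical units enter only at quantification). Default radius 1: the
  erosion is a separator of thin bridges, not a denoiser, and larger
  radii visibly bias volumes. Objects are *not* dilated back after
  erosion; measured volumes therefore underestimate the pre-erosion
  mask volume by roughly one surface shell per cell, uniformly across
  conditions.
- **Connected components** default to 26-connectivity (full box
  neighborhood), with 6 and 18 available; labels are assigned in
  deterministic raster-scan order.
- **Size filter**: objects with volume `< min_volume_vox` are removed
  (`≥` survives); surviving labels are not renumbered.
- **Watershed splitting**: objects larger than `split_threshold_vox`
  are re-segmented by marker-controlled watershed on the Euclidean
  distance transform of the object alone. Markers are distance-transform
  local maxima at least `watershed_min_seed_separation_vox` (default 5)
  apart, ties broken by scan order; a single marker leaves the object
  untouched. Fragments get fresh labels and replace the object in
  place, so the foreground voxel multiset is exactly conserved. The
  default threshold is adaptive — 8× the median object volume of the
  current map — because "too large to be one cell" is relative to the
  population; an absolute voxel count or `off` can be set instead. In
  test scenes with engineered touching pairs we pass an absolute
  threshold (~1.5× a single cell's volume, known from the generative
  parameters) because a 15-cell population median is itself inflated by
  the merged pairs.

## Region classification

A region map partitions the volume into BACKGROUND, NSRR and FRR. From
an NSRR-probability map, tissue voxels (by default the map's support,
or an explicit mask/cutoff) split at probability 0.5; the two-class
output format of region classifiers varies, so the tissue convention is
configurable.

Each object's overlap fractions with NSRR and FRR are exact integer
voxel-count ratios. An object is assigned the region whose fraction
reaches `inclusion_fraction` (default 0.5 — the "half or more of the
cell lies there" rule). At inclusion > 0.5 at most one region can
qualify, making assignment provably unique; at exactly 0.5 a perfect
0.5/0.5 tie is UNCLASSIFIED. BACKGROUND overlap never counts toward a
class: a cell mostly outside tissue becomes UNCLASSIFIED rather than
disappearing silently, and the downstream policy (`keep`/`drop`)
decides whether unclassified cells are analyzed separately or excluded.

## Quantification

Principal axes come from the eigen-decomposition of the object's voxel
coordinate covariance computed in physical µm coordinates (so
anisotropic z-spacing does not distort shape), with `spacing²/12` added
to each diagonal element — the variance of a uniform distribution over
one voxel — so voxels are treated as boxes rather than points and
one-voxel-thin objects keep finite axis ratios. Eigenvalues map to full
axis lengths by the uniform solid ellipsoid convention,
`axis = 2·sqrt(5·λ)`. Elongation `a/b` is the default "how
fiber-aligned is this cell" feature; ellipticity `1 − c/a` and
sphericity are also reported.

Surface area for sphericity counts exposed voxel faces weighted by
their physical areas. This estimator is voxelization-biased high (about
1.5× for a smooth sphere), so sphericity is comparable across objects
within a run but is not an absolute geometric quantity.

Intensity statistics are always taken from the raw channels, never from
thresholded data.

Stack summaries report percent volume (foreground voxels of a class ÷
denominator voxels × 100) and count per mm³. The denominator is either
the whole imaged stack (default — the simplest reading of "total sample
volume") or the NSRR∪FRR tissue voxels, because whole-mount fields
contain empty mountant; neither mode is claimed as the only valid one,
and the CLI exposes the choice.

## Validation scoring

Predictions are z-projected by column majority: each pixel takes the
label of the object owning the most voxels in its column (ties to the
smaller label). A predicted and an expert 2D object are linked when
their intersection covers at least half (configurable) of the *smaller*
footprint — robust to experts marking cells with dots or thin outlines
while predictions are filled. Expert point annotations can be dilated
to disks of a configurable radius first.

From the link multiplicities: under-segmentation = predicted objects
linked to ≥ 2 expert objects; over-segmentation = expert objects linked
to ≥ 2 predictions; missed/spurious = unlinked expert/predicted
objects; correct = mutual one-to-one links, so a merged pair is never
simultaneously "correct". The expert-to-prediction matching rule is a
documented package choice; published comparisons of this kind rarely
state one precisely.

## Synthetic scenes

The generator emulates exactly the features the pipeline's contracts
depend on: two tissue compartments (an FRR band spanning a fraction of
the y-extent, elongated in-plane cells with axis ratio 3–5; NSRR
remainder, rounder cells with ratio 1–1.5, both with minor radius 3–5
voxels), foreground/background intensities 200/20, Gaussian noise
σ = 4, multiplicative per-plane depth attenuation (default 1 % per
plane), optional engineered touching pairs (ball pairs at 0.75× the sum
of radii apart, overlap voxels owned by the nearer center), and extra
channels in which a chosen fraction of cells carries an intensity
offset (the tracer-uptake scenario). Default fields are 30 planes of
160²–192² pixels with ~30 cells — sizes chosen so full-pipeline checks
run in seconds while every contract (separation, splitting,
classification, scoring) is still exercised at realistic densities.

Cell placement rejection-samples against a voxel-gap constraint
(default 3 voxels) and, by default, against 2D footprint overlap, so
that projection-based scoring on truth is unambiguous. Everything is
driven by one `numpy` Generator seed; identical parameters give
byte-identical scenes.

Not emulated: PSF blur, Poisson-dominated photon noise (a Poisson-free
Gaussian model is the default; confocal noise is photon-limited, which
matters at low SNR), spectral bleed-through, ramified/crescent cell
morphology (a crescent is approximable as an ellipsoid minus an offset
ellipsoid but ships only as ellipsoids), and vasculature. Consequently,
passing the synthetic recovery tests shows the pipeline's logic is
correct and self-consistent — it does not certify detection accuracy on
real cleared-tissue stacks, where foreground models, not the pipeline
plumbing, dominate performance.

## I/O conventions

Axis order is (z, y, x), plane 0 = first TIFF page; multi-channel
stacks are plane-interleaved with channel names assigned by the
manifest. Label maps are written as 32-bit float TIFF holding exact
integers (the ImageJ 32-bit convention; exactness is asserted below
2²⁴). Voxel spacing is embedded on write and recovered on read; stacks
without spacing metadata default to (1, 1, 1) with a warning, making
physical-unit columns voxel-unit. The manifest is a strict line-oriented
`key: value` document: required keys `channels`, `target`; optional
`backend`, `probmap_pattern`, `region_source`, `region_pattern`,
`input_pattern`; unknown keys are errors so a misspelled key can never
silently select a default.

## Determinism

The only stochastic component is the scene generator, seeded
explicitly. Watershed seeding, connected-component labeling, Otsu
tie-breaks and table ordering are all made deterministic by
construction, so two runs of `ganglion3d run` on the same folder with
the same config produce byte-identical CSVs and label maps — this is
tested at file-digest level.
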