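# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates. It states no result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Moment-distance metrics

For a curve sampled at strictly increasing abscissa positions x_i with
reflectance ρ_i, and pivots λ_LP ≤ λ_RP lying on sample positions,

    MD_LP = Σ sqrt(ρ_i² + (x_i − λ_LP)²),   MD_RP = Σ sqrt(ρ_i² + (λ_RP − x_i)²)

summed over all samples with λ_LP ≤ x_i ≤ λ_RP, both pivots inclusive.
The derived quantities are MDI = MD_RP − MD_LP, MDIN = MDI/(MD_RP+MD_LP),
MDRLR = MD_LP/MD_RP and MDRRL = MD_RP/MD_LP. Exact identities used as
test oracles: MDRLR·MDRRL = 1, MDIN = (MDRRL−1)/(MDRRL+1),
MDI = MD_LP·(MDRRL−1); reversing the curve swaps the two pivot sums and
the two ratios and flips the sign of MDI and MDIN; MDIN ∈ (−1, 1) for any
strictly positive curve; widening the window never decreases either sum.

**Abscissa units.** The default abscissa is the retained-band ordinal
index 0, 1, 2, … — bands removed by the bad-band mask are dropped *before*
indexing, so the retained bands are contiguous. Wavelength-nm abscissae
are available (`units="nm"`). The choice matters: the equations mix
reflectance with abscissa distance, so the numbers change materially with
the unit convention.

**Reflectance scale.** For the same reason, the family's sensitivity to
curve *shape* depends on reflectance and abscissa being commensurate.
With reflectance in [0, 1] against an index abscissa spanning hundreds,
the abscissa legs dominate every hypotenuse and the metrics degenerate
toward functions of the band count alone. Hyperspectral products
conventionally store reflectance as 10⁴-scaled integers, which puts the
reflectance legs on the abscissa's scale; `md_cube` therefore accepts a
`reflectance_scale` multiplier (default 1 — the function computes exactly
what it is given) and the experiment pipeline defaults to
`md_reflectance_scale = 1e4` so that [0, 1] cubes are measured in that
native-DN regime. Per-curve `md_metrics` applies no hidden scaling.

**Degenerate cases.** A single-sample window (λ_LP = λ_RP) is legal and
gives MD = ρ, keeping the diagnostic sweep defined at its first step. A
zero MD (all-zero reflectance in a degenerate window) makes the ratios —
and MDIN when both sums are zero — undefined; they are reported as NaN
with a warning, never silently replaced. NaN reflectance inside the
window is an error unless `skip_nan=True`, which excludes those samples
and reports the used-sample count.

**The pivot sweep** (`md_sweep`) fixes one pivot at the curve's end and
grows the window one band at a time, returning the length-n sequence of
cumulative sums; plotted for two classes, the point where the curves
diverge localizes the wavelength region where their shapes differ.

## Comparison indices

Broadband means are unweighted averages over fixed windows — NIR
750–850 nm, red 600–700 nm, green 500–600 nm, blue 400–500 nm — so that
the same definition applies to any sensor. Narrow-band indices use the
nearest retained band to their nominal wavelengths (NDII: 819/1649 nm;
PRI: 529/580 nm), ties resolving to the shorter wavelength; a target
outside the cube's wavelength span is an error naming the index.

Two deliberate fidelity choices: NDVI is implemented as
(Red−NIR)/(Red+NIR) — the orientation the experiment tables use — with a
`standard_orientation` flag for the conventional sign, since tree-based
classifiers are insensitive to a monotone flip (the tests verify
agreement up to split-threshold placement, not bit equality, because CART
thresholds inside inter-class gaps are not mirror-symmetric). PSRI is the
broadband (Red−Blue)/NIR variant, and EVI uses the canonical constants
G = 2.5, L = 1, C1 = 6, C2 = 7.5.

## Texture features

The cube's retained bands are reduced by PCA (band covariance over
NaN-free pixels, mean-centred; eigenvector signs fixed by making the
largest-magnitude loading positive) and the top three score images are
retained. For each, five statistics of the windowed gray-level
co-occurrence matrix are computed: CON = Σ(i−j)²P, ASM = ΣP²,
ENT = −ΣP ln P (0·ln 0 ≡ 0), VAR = Σ(i−μ)²P, COR = covariance/σ², NaN on
constant windows. The matrix at a pixel counts all ordered level pairs at
the configured offset whose both endpoints fall inside the window, one
symmetrized and normalized matrix per direction (0°, 45°, 90°, 135°),
averaged over the four directions.

Defaults — 32 levels, offset 1, 7×7 window — follow common co-occurrence
practice and are configurable; quantization is equal-width between the
image's 1st and 99th percentile with clipping, and borders are
reflect-padded. A brute-force pair-enumeration oracle validates the
vectorized implementation on small fixtures.

## Segmentation

Object geometry comes from deterministic hierarchical region merging on
the full 25-layer feature stack (indices + MD layers + textures), each
layer z-scored first. Starting from single-pixel regions, the globally
cheapest 4-adjacent pair — RMS distance between region mean vectors —
merges repeatedly; the hierarchy is cut when the cheapest remaining merge
exceeds `scale × 0.05` (standardized RMS units). Because the merge
sequence is independent of the cut, a larger scale always continues the
same sequence, so the segment count is non-increasing in scale by
construction; ties in cost break on region ids, making results
bit-reproducible. NaN pixels are excluded from merging and attached to
the nearest valid segment afterwards.

This is an approximation standing in for proprietary segmentation tools
whose cost functions are unpublished; scale values are therefore
calibration-specific to this implementation and not comparable across
tools. Low scales over-segment (many near-pixel objects), which is
harmless for the downstream classifier; the experiments default to
scale 5.

## Classification experiment

Per-object means of every layer (NaN-excluding, with contributing-pixel
counts) form the object table; each object's label is the modal
ground-truth class over its labeled pixels (ties to the smaller class id,
0 = unlabeled). A stratified split sends round(0.3·n_c) objects per class
to training. The classifier is a 500-tree CART random forest with √F
candidate features per split and unlimited depth. Variable importance is
permutation importance on the test objects — mean accuracy decrease over
8 permutations, normalized by its standard deviation (Gini importance by
flag); evaluation is capped at 256 objects per repeat to keep the pass
tractable on over-segmented scenes. Accuracy is reported object-weighted
and pixel-weighted (objects weighted by size); McNemar's
Z = (f12 − f21)/√(f12 + f21) compares any two sets on the shared test
objects, significance flagged at |Z| > 1.96, raw (no multiple-testing
correction, configurable). All randomness flows from one seed; the whole
experiment is bit-stable under a fixed seed and config.

## Synthetic scenes

A scene is a patchwork of field-like regions (a jittered 10×10 grid on a
64×64 raster by default) over 100 bands spanning 400–1700 nm — wide
enough that the NDII (1649 nm) and PRI bands exist. Class spectra are
piecewise-linear templates: a green-vegetation curve (green peak, red
trough, red-edge rise, NIR plateau, SWIR decline), a 0.7-amplitude
variant, and a soil/residue pair. Pixels get a multiplicative brightness
factor (sd 0.05 — illumination/moisture variability; it dominates the
principal components, as brightness does in real imagery, and pushes the
pair's subtle contrast out of the top-3 PC span so the texture branch
cannot alias it) plus per-band Gaussian noise (sd 0.01), clipped to
[0, 1].

The confusable pair is built by adding to one copy of the soil template a
compact quadratic absorption dip (centre 450 nm, width 80 nm, depth 0.15
by default) plus a uniform compensating offset over the containing
broadband window, sized on the actual band grid so the two classes'
broadband means agree to ≤1e−6 over all four windows. Consequently NDVI,
EVI, NRI and PSRI are identical for the pair by construction, the NDII
and PRI narrow bands are untouched by a blue-range dip, and only the MD
layers carry the contrast. The dip parameters were sized by a one-off
signal-to-noise analysis (pixel-level MDRRL contrast ≈ 4× its noise under
the default noise and brightness settings) so that the pair is separable
at object level but invisible to the baseline feature set. The generator
is not a radiative-transfer model: passing tests demonstrate the
pipeline's mechanics and the shape-vs-broadband contrast they were
designed to probe, not performance on real scenes (no mixed pixels, no
atmosphere, no spatially correlated noise).

## Problem sizes

The acceptance experiments use ten seeds of the default 64×64×100 scene
(≈ 2 000–3 000 objects each) — small enough to run the ten-fold
experiment ladder in a few minutes on one CPU while leaving every stage's
behaviour (segmentation geometry, importance rankings, McNemar
significance) qualitatively stable across seeds.

## Known limitations

* Scale values of the region merge are not comparable with eCognition /
  GRASS scale parameters; only the monotone fewer-larger-segments
  contract is shared.
* Permutation importance on test objects (rather than out-of-bag
  samples) slightly favours features that generalize; rankings agree for
  strongly separating layers.
* The MD shape sensitivity analysis (reflectance-scale regime) is
  specific to index-unit abscissae; nm-unit abscissae shift the regime.
* GLCM features on quantized PC scores can alias small region-mean
  differences via bin-edge effects when the scene has too little
  brightness variance; the generator's brightness field models the
  realistic case, but unusually clean scenes may leak such contrasts into
  the texture branch.
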