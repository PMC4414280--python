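# Methods

## The measurement model

The package quantifies wing color pattern as three coefficient sets per
specimen, each capturing one aspect of the phenotype:

1. **Shape/position** — 50 landmarks per wing, Procrustes-superimposed,
   200 coefficients per specimen;
2. **Color** — 63 hierarchical chromaticity coefficients;
3. **Patterning** — 510 Gabor wavelet coefficients.

Wingform separation is then measured by DAPC (PCA followed by LDA) with
contribution vectors and centroid Mahalanobis distances, and the three
blocks concatenate into a continuous character matrix for parsimony
analysis.  Everything below records the concrete modelling and numerical
choices, their defaults, and what they do or do not let the tests show.

## Synthetic wing generator

The generator emulates scans of excised fore- and hindwings on a light
uniform background.  A wing is a fixed 14-vertex outline with a ~4:1
length:depth aspect ratio, six longitudinal reference polylines
(anterior edge, four internal veins at depth fractions 0.2/0.4/0.6/0.8,
posterior edge) drawn as dark strokes, and up to six transverse color
bands.  Bands are numbered I–VI from the apex toward the base — band I
is adjacent to the apex (LM 7), band VI to the base (LMs 1/14) — and
`band_center` is a fraction of wing length measured from the apex, so
centers increase with band number.

Defaults define the study conditions: seven wingform presets (five male,
two female); band width 0.08 of wing length; positional jitter
`jitter_sd = 0.01` (SD of a per-band center shift, as a fraction of wing
length, clipped so strips never overlap); color noise
`color_noise_sd = 0.02` (SD of a per-band, per-channel color offset,
plus per-pixel noise at half that SD).  These magnitudes were chosen
once as a realistic within-form variation scale — band positions in
real wings vary by a few percent of wing length and scanner/pigment
variation shifts channel values by a few percent — and are not tuned.
Palette: black (0.05, 0.05, 0.05), white (0.97, 0.97, 0.97), yellow
(0.90, 0.80, 0.10), orange (0.90, 0.50, 0.10); "hyaline" renders as the
unpigmented bluish-gray membrane (0.80, 0.82, 0.85) against a 0.93
near-white background.  Black and white are deliberately achromatic:
adding or removing a black band barely changes chromaticity, which is
exactly the property that makes the single-band-presence wingform pair
a chromaticity-hard, landmark-easy discrimination (and vice versa for
the color-only pair).

Two presets differ only in the presence of one medial band
(`victoriaM`/`neopictaM`), two only in band colors with identical
geometry (`victoriaM`/`ornataM`); one preset has a fully unbanded
forewing (`ornataF`) and one a fully unbanded hindwing (`spaeteriM`),
exercising the fully-collapsed landmark path in every default cohort.

Determinism: one master seed; per-specimen seeds derive from
`SeedSequence([master, index])`.  Identical (spec, length, seed) triples
render byte-identical images.  Per-band color offsets are drawn whether
or not the band is present, so RNG streams stay aligned across presets.

What the generator does **not** emulate: real venation networks (the
reference veins are smooth generic polylines, not homologous named
veins), iridescence/specular highlights, scanning artifacts (JPEG
blocking, dust, shadows), wing damage, and landmarking error (truth
landmarks are exact).  Passing end-to-end tests therefore demonstrates
the pipeline's correctness and sensitivity structure, not its
robustness to digitization noise on real scans — real landmarks enter
through TPS files, as in practice.

## Image squaring

Segmentation: background color from the border median (or an explicit
hint); foreground where the Euclidean RGB distance from background
exceeds an Otsu threshold; morphological closing; largest connected
component; interior holes (hyaline cells) filled.  Area must be 1–90% of
the frame, otherwise a `SegmentationError` asks for a manual mask.

Leveling: the costa orientation is the slope of a least-squares line
through the uppermost mask pixel per column (central 80% of columns),
applied iteratively (two passes) with bilinear rotation.  Rescale to a
512-column span, bilinear; a wing taller than 256 px after rescale is an
aspect-ratio error.  Placement is flush-left with the wing's top edge at
the top of its half (forewing upper, hindwing lower) — the placement
within each half is otherwise unconstrained, and flush-left/top was
fixed once for reproducibility.  Outside the masks the composite is
exact black.  Grayscale uses ITU-R 601 weights (0.299, 0.587, 0.114),
configurable.

## Landmarks and collapse protocol

LMs 1–14 are structural outline points (LM 1 anterior base corner, LM 7
apex, LM 14 posterior base corner); LMs 15–50 are six points per band
(bands I–VI), ordered anterior→posterior along the six reference lines.
The reference veins are treated as six ordered slots rather than named
homologies.

Collapse rules (template split between bands III and IV):

- missing band among I–III → points of the next existing band on the
  apical side; band I (or a band with no existing apical neighbour
  within I–III) → all six points at LM 7;
- missing band among IV–VI → points of the next existing band on the
  basal side; band VI (or no basal neighbour) → upper three points at
  LM 1, lower three at LM 14;
- a band not reaching the anterior/posterior edge → uncovered edge
  points move medially to the band's intersection with the nearest
  covered reference vein.

The apical/basal directions were fixed from the terminal rules (band I
terminates at the apex landmark, band VI at the base landmarks), which
determine the band numbering direction unambiguously.  Collapse is
idempotent and never invents coordinates.

GPA: center to the origin, scale to unit centroid size, rotate
(reflections excluded) onto a consensus initialized from the first
specimen; re-estimate the consensus until it moves < 1e-8 (max 100
iterations).  Fore- and hindwings are aligned separately and
concatenated fore-then-hind, x1,y1,…,x50,y50 each, to 200 coefficients.
Landmark numbering is 1-based at I/O boundaries (TPS, reports), 0-based
internally.

## Chromaticity

Per-pixel chromaticities are averaged per region (not chromaticity of
mean channels), so each region triple sums to exactly 1 and the vector
is invariant under any global positive scaling of the image.  Means are
taken over wing-mask pixels only; the black background would otherwise
inject the degenerate neutral triple into small regions.  R+G+B = 0 maps
to (1/3, 1/3, 1/3); regions without wing pixels get the same value and
are flagged.  Wing thirds cut the 512 columns at 171 and 341 (fixed
integer cuts for bit-reproducibility); halves split each third at its
wing-half midline (rows 128 and 384).

## Gabor bank

Carrier wavelength = diameter/2 (two cycles across the support),
Gaussian envelope σ = diameter/4, support truncated at the stated
diameter (circular).  The real (even) component is DC-corrected to zero
mean over its support; the imaginary (odd) component is zero-mean by
symmetry.  Both are L2-normalized so magnitudes compare across scales.
Coefficients are raw signed inner products — real and imaginary are kept
separately, not combined into magnitudes.  Ordering is (scale desc,
row-major position, rotation asc, real-then-imaginary), so index ↔ wing
location is deterministic for contribution maps.  Placements tile the
square exactly (1×1 at 512, 2×2 at 256, 4×4 at 128, 8×8 at 64), so
patches never cross image borders.

## DAPC, contributions, Mahalanobis

PCA is covariance PCA (centered, unscaled) retaining
min(n−1, p, 50) components; components with variance below 1e-9 of the
leading one are dropped — they carry no signal and would make the
within-group scatter singular.  LDA uses the eigen solver; if the
within-group scatter is still singular, the fit is retried with
shrinkage 1e-6 and a warning.  Discriminant axes are sign-fixed so each
axis's largest-magnitude loading is positive.  Contribution vectors are
|PC loadings × LD loadings|, column-normalized; top-k reports break ties
by (contribution desc, column index asc).

Mahalanobis distances use all g−1 axes and the pooled within-group
covariance of the discriminant scores (residual-d.f. weighting), so
values are in standard deviations.  On synthetic cohorts the within-form
variation is only the generator's jitter/noise, so MDs run far larger
than on real specimens; the relative ordering across feature sets, not
the absolute magnitude, is the meaningful output there.  Leave-one-out
assignment refits the whole DAPC without the held-out specimen and
assigns it to the nearest centroid by Mahalanobis distance.

## Character matrix

Blocks concatenate to 773 candidate characters; all-zero characters are
dropped (on synthetic squares many fine-scale Gabor cells lie wholly on
black background and are exactly zero); remaining characters are
z-standardized (sample SD), min-max rescaled to [0, 1], and rounded to
three decimals (half-even, via `np.round`, for platform stability).  A
constant non-zero character has no z-score; it is kept at the midpoint
0.5 and logged rather than silently dropped (configurable by dropping
logged columns downstream).  Constancy is detected as max = min, not
SD = 0, to be robust to 1e-17-scale rounding in the SD of identical
values.  Exports: a TNT continuous block and NEXUS continuous datatype
(via dendropy); both round-trip exactly at three decimals.  By default
the matrix covers male wingforms only, matching how such matrices are
used for species-level parsimony.

## Problem sizes

Default study cohort: 7 wingforms × 10 specimens at 512-px wing length —
large enough that DAPC retains the full 50 PCs for the combined set and
leave-one-out refits are meaningful, small enough to run in well under a
minute.  The jitter-sensitivity check uses 7 × 3 cohorts at 256 px over
three jitter levels and two seeds, a deliberately lighter setting since
it only compares accuracies across conditions.

## Known limitations

- No automatic landmark detection on real scans; landmarks come from TPS
  files produced by standard landmarking software.
- The reference-vein slots are generic; mapping results onto named
  venation requires the user's homology decisions.
- Mahalanobis magnitudes on near-noiseless synthetic data are not
  comparable to values from biological specimens (see above).
- The one manual-masking escape hatch is an externally supplied mask,
  not an interactive tool.
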