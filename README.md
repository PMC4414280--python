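# wingquant

Quantification of banded insect wing color patterns, built for damselfly
wing polymorphism studies in which discrete "wingforms" (species × sex
phenotypes) differ in which transverse color bands they carry and in the
colors of those bands.  Wing scans are reduced to three complementary
coefficient sets per specimen, the wingforms are discriminated, and the
coefficients export as a continuous character matrix for parsimony
software.

The three feature sets are:

- **Landmark geometry (200 coefficients).**  A fixed 50-landmark template
  per wing — 14 structural outline/vein points and 6 points per band for
  bands I–VI, placed where each band's proximal edge crosses six
  longitudinal reference veins.  Wings missing bands are brought onto the
  template by a standardized *collapse* protocol (missing distal bands
  collapse apically, terminating at the apex landmark LM 7; missing
  proximal bands collapse basally, terminating at the base landmarks
  LM 1/LM 14; truncated bands collapse medially to the nearest covered
  vein).  Configurations are superimposed by generalized Procrustes
  analysis, removing translation, scale and rotation, and concatenated as
  fore + hind (x, y) coordinates: 2 × 50 × 2 = 200 coefficients.
- **Chromaticity (63 coefficients).**  Each pixel's RGB maps to
  luminance-free chromaticity coordinates r = R/(R+G+B), g = G/(R+G+B),
  b = B/(R+G+B); mean triples are taken over a hierarchy of 21
  sub-images of the standardized square (whole image, each wing, wing
  thirds, and anterior/posterior halves of each third): 21 × 3 = 63.
- **Gabor wavelet patterning (510 coefficients).**  The grayscale square
  is projected onto a bank of Gabor wavelets tiling it at four scales
  (512, 256, 128, 64 px diameter; 1 + 4 + 16 + 64 = 85 placements), three
  rotations (0°, 120°, 240°) and two components (real, imaginary):
  85 × 3 × 2 = 510 signed coefficients.

Feature sets (individually and combined) are compared by **discriminant
analysis of principal components (DAPC)**: covariance PCA retaining the
first 50 components, then linear discriminant analysis on the PC scores
(g wingforms → g−1 axes).  Contribution vectors
|PC loadings × LD loadings| (column-normalized to proportions) map each
discriminant axis back to wing locations, and Mahalanobis distances
between wingform centroids under the pooled within-group covariance —
i.e. in standard-deviation units — summarize pairwise separation.

A synthetic banded-wing generator ships with the package: seven wingform
presets (five male, two female) built from six possible bands per wing,
colored from {black, white, yellow, orange, hyaline}, with positional
jitter and color noise, rendered with exact ground-truth landmarks and
masks.  Two preset pairs are diagnostic by construction: one pair differs
only in the presence of a single medial band, one pair shares identical
band geometry and differs only in band colors.

## Worked example

```python
import wingquant as wq
from wingquant.pipeline import extract_features
from wingquant.discriminant import dapc_fit, mahalanobis_matrix, loo_assignment_accuracy

library = wq.make_wingform_library()              # 7 wingform presets
specimens, labels = wq.generate_cohort(library, n_per_form=10, seed=1)
feats = extract_features(specimens)               # imaging + 3 feature sets

res = dapc_fit(feats["matrices"]["ALL"])          # 7 groups -> 6 axes
print(res.n_axes)                                 # 6
print(loo_assignment_accuracy(feats["matrices"]["ALL"]))   # 1.0

md_chrm = mahalanobis_matrix(dapc_fit(feats["matrices"]["CHRM"]))
md_lm = mahalanobis_matrix(dapc_fit(feats["matrices"]["LM"]))
print(round(md_chrm.loc["victoriaM", "ornataM"], 2))   # 11.57
print(round(md_lm.loc["victoriaM", "ornataM"], 2))     # 2.3
```

The last two numbers show the designed contrast: `victoriaM` and
`ornataM` share band geometry and differ only in band colors, so
chromaticity separates them (MD 11.57 standard deviations) far better
than landmarks do (MD 2.30).  For the single-band-presence pair
(`victoriaM` vs `neopictaM`) the ranking inverts: landmark MD 131.3
versus chromaticity MD 1.35, because an added black band barely moves
the (luminance-free) chromaticities but strongly moves band landmarks.
Leave-one-out nearest-centroid assignment in discriminant space recovers
every generator label (accuracy 1.0).

The same pipeline runs from the shell:

```sh
wingquant run --n-per-form 10 --seed 1 --out run_dir
```

writing feature tables, DAPC scores, contribution tables, Mahalanobis
tables with a per-pair summary, per-wingform mean shapes, and the
character matrix in TNT and NEXUS dialects.  Real scans are supplied via
`--input manifest.csv` (columns `specimen_id, wingform, fore_image,
hind_image, fore_tps, hind_tps`), with landmarks read from TPS files.

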