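"""Synthetic banded-wing generator.

Renders damselfly-like wings as RGB arrays with known ground truth: a fixed
14-vertex outline, six longitudinal reference polylines (anterior edge, four
internal veins, posterior edge), and up to six transverse color bands
(numbered I-VI from the wing apex toward the base).  Every rendered specimen
carries its true 50-landmark configuration (14 structural outline points plus
6 points per band), with absent or truncated bands already collapsed by the
standard protocol, so the full downstream pipeline - segmentation, squaring,
Procrustes, chromaticity, Gabor wavelets, discriminant analysis - can be
exercised and scored against generator truth.

Band positions are expressed as fractions of wing length measured from the
apex (distal end), so ``band_center`` is strictly increasing in band order
I -> VI.  Colors come from a five-entry palette (black, white, yellow,
orange, hyaline); hyaline renders as the unpigmented membrane tint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import collapse_bands

__all__ = [
    "PALETTE",
    "BACKGROUND_RGB",
    "MEMBRANE_RGB",
    "VEIN_RGB",
    "WingSpec",
    "WingformSpec",
    "SyntheticSpecimen",
    "make_wingform_library",
    "render_specimen",
    "render_wing",
    "generate_cohort",
]

# Rendering palette.  Chosen to be linearly separable in chromaticity space:
# black and white are achromatic, yellow and orange sit in distinct corners
# of the (r, g) chromaticity plane, hyaline is the faint bluish membrane tint.
BACKGROUND_RGB = (0.93, 0.93, 0.93)
MEMBRANE_RGB = (0.80, 0.82, 0.85)
VEIN_RGB = (0.22, 0.15, 0.10)
PALETTE = {
    "black": (0.05, 0.05, 0.05),
    "white": (0.97, 0.97, 0.97),
    "yellow": (0.90, 0.80, 0.10),
    "orange": (0.90, 0.50, 0.10),
    "hyaline": MEMBRANE_RGB,
}

N_BANDS = 6
N_OUTLINE = 14
N_REFLINES = 6
N_LANDMARKS = 50

# Normalized outline vertices (x along wing length in [0, 1], base at x=0 and
# apex at x=1; y is depth in [0, 1] from anterior to posterior, later scaled
# by the wing aspect).  LM 1 = anterior base corner, LM 7 = apex (outermost
# point), LM 14 = posterior base corner.
_OUTLINE_NORM = np.array(
    [
        (0.00, 0.30),  # LM 1
        (0.04, 0.12),  # LM 2
        (0.18, 0.05),  # LM 3
        (0.38, 0.01),  # LM 4
        (0.58, 0.00),  # LM 5
        (0.80, 0.02),  # LM 6
        (1.00, 0.22),  # LM 7 (apex)
        (0.93, 0.58),  # LM 8
        (0.80, 0.80),  # LM 9
        (0.62, 0.93),  # LM 10
        (0.44, 1.00),  # LM 11
        (0.26, 0.93),  # LM 12
        (0.10, 0.72),  # LM 13
        (0.01, 0.44),  # LM 14
    ]
)

# Depth fractions of the six reference polylines (0 = anterior edge,
# 1 = posterior edge; interior values are the four internal veins).
_REFLINE_FRACTIONS = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

ASPECT = 0.25  # wing depth / wing length


class SpecError(ValueError):
    """A wingform specification violates its invariants."""


@dataclass(frozen=True)
class WingSpec:
    """Band layout of a single wing.

    Arrays are indexed by band number I..VI (0..5); band I is the distal-most
    band.  ``band_center`` is the distance of the band's strip center from
    the wing apex as a fraction of wing length; ``band_extent`` gives
    (anterior, posterior) truncation fractions of wing depth - (0, 0) means
    the band spans the full anteroposterior depth.
    """

    band_present: tuple[bool, ...]
    band_color: tuple[str, ...]
    band_center: tuple[float, ...]
    band_width: tuple[float, ...] = (0.08,) * N_BANDS
    band_extent: tuple[tuple[float, float], ...] = ((0.0, 0.0),) * N_BANDS

    def validate(self) -> None:
        for name in ("band_present", "band_color", "band_center", "band_width", "band_extent"):
            if len(getattr(self, name)) != N_BANDS:
                raise SpecError(f"{name} must have exactly {N_BANDS} entries")
        for c in self.band_color:
            if c not in PALETTE:
                raise SpecError(f"unknown palette color {c!r}")
        for v in self.band_center + self.band_width:
            if not 0.0 <= v <= 1.0:
                raise SpecError("band fractions must lie in [0, 1]")
        for a, p in self.band_extent:
            if not (0.0 <= a <= 1.0 and 0.0 <= p <= 1.0 and a + p < 1.0):
                raise SpecError("band extents must lie in [0, 1] with a + p < 1")
        present = [i for i in range(N_BANDS) if self.band_present[i]]
        centers = [self.band_center[i] for i in present]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise SpecError("band_center must be strictly increasing among present bands")
        # non-overlap of present strips
        for (i, j) in zip(present, present[1:]):
            lo = self.band_center[i] + self.band_width[i] / 2
            hi = self.band_center[j] - self.band_width[j] / 2
            if lo >= hi:
                raise SpecError(f"bands {i + 1} and {j + 1} overlap")


@dataclass(frozen=True)
class WingformSpec:
    """Generative description of one wingform (species x sex phenotype)."""

    name: str
    fore: WingSpec
    hind: WingSpec
    jitter_sd: float = 0.01
    color_noise_sd: float = 0.02

    def validate(self) -> None:
        if self.jitter_sd < 0 or self.color_noise_sd < 0:
            raise SpecError("noise magnitudes must be non-negative")
        self.fore.validate()
        self.hind.validate()


@dataclass
class SyntheticSpecimen:
    """One rendered specimen: fore/hind RGB images plus ground truth."""

    specimen_id: str
    wingform: str
    fore_image: np.ndarray
    hind_image: np.ndarray
    truth_fore_lms: np.ndarray  # (50, 2) (x, y) pixel coordinates
    truth_hind_lms: np.ndarray
    truth_fore_mask: np.ndarray  # boolean, true wing region incl. veins
    truth_hind_mask: np.ndarray
    seed: int


def _edges(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Anterior and posterior outline depth at normalized positions ``xs``."""
    up = _OUTLINE_NORM[:7]
    lo = _OUTLINE_NORM[6:][::-1]  # LM14 .. LM8, LM7 with increasing x
    yu = np.interp(xs, up[:, 0], up[:, 1])
    yd = np.interp(xs, lo[:, 0], lo[:, 1])
    return yu, yd


def _refline_depth(frac: float, xs: np.ndarray) -> np.ndarray:
    yu, yd = _edges(xs)
    return yu + frac * (yd - yu)


def _jittered_centers(wing: WingSpec, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Apply positional jitter, clipped so present strips stay disjoint in [0, 1]."""
    centers = np.array(wing.band_center, dtype=float)
    if jitter_sd == 0:
        return centers
    eps = rng.normal(0.0, jitter_sd, N_BANDS)
    present = [i for i in range(N_BANDS) if wing.band_present[i]]
    half = np.array(wing.band_width) / 2
    for i in present:
        lo, hi = half[i], 1.0 - half[i]
        k = present.index(i)
        if k > 0:
            j = present[k - 1]
            lo = max(lo, (centers[i] + centers[j]) / 2 + half[i])
        if k < len(present) - 1:
            j = present[k + 1]
            hi = min(hi, (centers[i] + centers[j]) / 2 - half[i])
        centers[i] = np.clip(centers[i] + eps[i], lo, hi)
    return centers


def _band_intersections(
    wing: WingSpec, centers: np.ndarray, length_px: int, margin: int
) -> tuple[list, list[tuple[int, int]]]:
    """Raw band-landmark intersections (proximal band edge x reference lines).

    Returns, per band, a (6, 2) array with NaN rows for reference lines not
    covered by the band's extent (or None for absent bands), plus the covered
    (first, last) reference-line index per band.
    """
    hs = ASPECT * length_px
    inters: list = []
    ranges: list[tuple[int, int]] = []
    for b in range(N_BANDS):
        if not wing.band_present[b]:
            inters.append(None)
            ranges.append((0, N_REFLINES - 1))
            continue
        a_tr, p_tr = wing.band_extent[b]
        covered = np.flatnonzero(
            (_REFLINE_FRACTIONS >= a_tr - 1e-12) & (_REFLINE_FRACTIONS <= 1 - p_tr + 1e-12)
        )
        if covered.size == 0:
            raise SpecError(f"band {b + 1} extent covers no reference vein")
        # proximal edge of the strip = larger distance from apex
        x_prox = 1.0 - (centers[b] + wing.band_width[b] / 2)
        pts = np.full((N_REFLINES, 2), np.nan)
        for i in covered:
            y = _refline_depth(_REFLINE_FRACTIONS[i], np.array([x_prox]))[0]
            pts[i] = (margin + x_prox * length_px, margin + y * hs)
        inters.append(pts)
        ranges.append((int(covered[0]), int(covered[-1])))
    return inters, ranges


def render_wing(
    wing: WingSpec,
    length_px: int,
    rng: np.random.Generator,
    jitter_sd: float,
    color_noise_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one wing; returns (image, true mask, 50 truth landmarks)."""
    if length_px < 64:
        raise ValueError("length_px must be >= 64")
    wing.validate()

    margin = max(8, length_px // 16)
    hs = ASPECT * length_px
    width = length_px + 2 * margin
    height = int(round(hs)) + 2 * margin

    xs = (np.arange(width) - margin + 0.5) / length_px  # normalized x per column
    ys = (np.arange(height) - margin + 0.5) / hs  # normalized depth per row
    yu, yd = _edges(np.clip(xs, 0, 1))
    in_span = (xs >= 0) & (xs <= 1)
    span = np.where(yd - yu > 0, yd - yu, np.inf)
    depth = (ys[:, None] - yu[None, :]) / span[None, :]
    interior = in_span[None, :] & (depth >= 0) & (depth <= 1)

    img = np.empty((height, width, 3))
    img[:] = BACKGROUND_RGB
    img[interior] = MEMBRANE_RGB

    centers = _jittered_centers(wing, jitter_sd, rng)
    for b in range(N_BANDS):
        # Band color offsets drawn unconditionally so the RNG stream does not
        # depend on band presence (keeps per-form streams aligned).
        offset = rng.normal(0.0, color_noise_sd, 3)
        if not wing.band_present[b]:
            continue
        a_tr, p_tr = wing.band_extent[b]
        x0 = 1.0 - (centers[b] + wing.band_width[b] / 2)
        x1 = 1.0 - (centers[b] - wing.band_width[b] / 2)
        strip = (
            interior
            & (xs[None, :] >= x0)
            & (xs[None, :] <= x1)
            & (depth >= a_tr)
            & (depth <= 1 - p_tr)
        )
        color = np.clip(np.asarray(PALETTE[wing.band_color[b]]) + offset, 0, 1)
        img[strip] = color

    if color_noise_sd > 0:
        noise = rng.normal(0.0, color_noise_sd / 2, img.shape)
        img[interior] = np.clip(img[interior] + noise[interior], 0, 1)

    # Veins and outline drawn last, crisp.  Thickness scales with resolution.
    t = max(1.0, length_px / 340.0)
    rows_px = np.arange(height) + 0.5
    veins = np.zeros_like(interior)
    for frac in _REFLINE_FRACTIONS:
        line = margin + _refline_depth(frac, np.clip(xs, 0, 1)) * hs
        near = np.abs(rows_px[:, None] - line[None, :]) <= t / 2 + 0.5
        veins |= near & in_span[None, :] & (depth >= -0.02) & (depth <= 1.02)
    # close the base edge
    veins |= interior & ((xs >= 0) & (xs <= t / length_px))[None, :]
    img[veins] = VEIN_RGB

    mask = interior | veins

    # Truth landmarks: outline vertices + collapsed band points.
    outline = np.column_stack(
        (
            margin + _OUTLINE_NORM[:, 0] * length_px,
            margin + _OUTLINE_NORM[:, 1] * hs,
        )
    )
    inters, ranges = _band_intersections(wing, centers, length_px, margin)
    lmset = collapse_bands(inters, list(wing.band_present), ranges, outline)
    return img, mask, lmset.coords.copy()


def make_wingform_library() -> list[WingformSpec]:
    """The seven study wingforms (five male, two female), as fixed presets.

    The presets encode the diagnostic structure of the study system:
    ``victoriaM`` and ``neopictaM`` differ only in the presence of the single
    medial band III; ``victoriaM`` and ``ornataM`` share identical band
    geometry and differ only in band colors.  ``ornataF`` carries a fully
    unbanded forewing and ``spaeteriM`` a fully unbanded hindwing, so the
    fully-collapsed landmark path is exercised by default cohorts.
    """

    def wing(present, colors, centers=(0.12, 0.26, 0.40, 0.58, 0.74, 0.88)):
        return WingSpec(
            band_present=tuple(present),
            band_color=tuple(colors),
            band_center=tuple(centers),
        )

    absent = wing(
        (False,) * 6, ("hyaline",) * 6
    )
    neo_m = wing(
        (True, True, False, False, False, False),
        ("black", "white", "hyaline", "hyaline", "hyaline", "hyaline"),
    )
    vic_m = wing(
        (True, True, True, False, False, False),
        ("black", "white", "black", "hyaline", "hyaline", "hyaline"),
    )
    orn_m = wing(
        (True, True, True, False, False, False),
        ("black", "yellow", "orange", "hyaline", "hyaline", "hyaline"),
    )
    aur_m = wing(
        (True, False, True, False, True, False),
        ("black", "hyaline", "orange", "hyaline", "yellow", "hyaline"),
    )
    neo_f = wing(
        (False, True, False, True, False, True),
        ("hyaline", "orange", "hyaline", "black", "hyaline", "yellow"),
    )
    orn_f_hind = wing(
        (True, False, False, True, False, False),
        ("black", "hyaline", "hyaline", "orange", "hyaline", "hyaline"),
    )
    spa_m_fore = wing(
        (True, False, False, False, True, False),
        ("black", "hyaline", "hyaline", "hyaline", "white", "hyaline"),
    )
    return [
        WingformSpec("auroraM", fore=aur_m, hind=aur_m),
        WingformSpec("neopictaM", fore=neo_m, hind=neo_m),
        WingformSpec("neopictaF", fore=neo_f, hind=neo_f),
        WingformSpec("ornataM", fore=orn_m, hind=orn_m),
        WingformSpec("ornataF", fore=absent, hind=orn_f_hind),
        WingformSpec("spaeteriM", fore=spa_m_fore, hind=absent),
        WingformSpec("victoriaM", fore=vic_m, hind=vic_m),
    ]


def render_specimen(
    spec: WingformSpec, length_px: int = 512, seed: int = 0, specimen_id: str | None = None
) -> SyntheticSpecimen:
    """Render both wings of one specimen reproducibly from ``seed``."""
    if length_px <= 0:
        raise ValueError("length_px must be positive")
    spec.validate()
    rng = np.random.default_rng(seed)
    fore_img, fore_mask, fore_lms = render_wing(
        spec.fore, length_px, rng, spec.jitter_sd, spec.color_noise_sd
    )
    hind_img, hind_mask, hind_lms = render_wing(
        spec.hind, length_px, rng, spec.jitter_sd, spec.color_noise_sd
    )
    return SyntheticSpecimen(
        specimen_id=specimen_id or f"{spec.name}_s{seed}",
        wingform=spec.name,
        fore_image=fore_img,
        hind_image=hind_img,
        truth_fore_lms=fore_lms,
        truth_hind_lms=hind_lms,
        truth_fore_mask=fore_mask,
        truth_hind_mask=hind_mask,
        seed=seed,
    )


def specimen_seed(master_seed: int, index: int) -> int:
    """Reproducible per-specimen seed derived from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    library: list[WingformSpec],
    n_per_form: int,
    seed: int = 0,
    length_px: int = 512,
) -> tuple[list[SyntheticSpecimen], pd.DataFrame]:
    """Balanced cohort: ``n_per_form`` specimens of every wingform in ``library``."""
    if not library:
        raise ValueError("wingform library is empty")
    if n_per_form < 1:
        raise ValueError("n_per_form must be >= 1")
    specimens: list[SyntheticSpecimen] = []
    rows = []
    idx = 0
    for form in library:
        for k in range(n_per_form):
            s = specimen_seed(seed, idx)
            sp = render_specimen(
                form, length_px=length_px, seed=s, specimen_id=f"{form.name}_{k:02d}"
            )
            specimens.append(sp)
            rows.append({"specimen_id": sp.specimen_id, "wingform": form.name, "seed": s})
            idx += 1
    return specimens, pd.DataFrame(rows)
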