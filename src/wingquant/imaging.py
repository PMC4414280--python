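"""Standardization of raw wing scans into the 512-px composite square.

A scan of an excised wing on a light uniform background is segmented
(largest connected foreground component, interior hyaline cells retained by
hole filling), rotated so the upper wing margin (costa) is horizontal,
rescaled so the wing spans exactly 512 columns, and composed into a
512x512 RGB square on an exact-black background with the forewing at the
top of the upper half and the hindwing at the top of the lower half -
the input expected by the chromaticity and Gabor-wavelet analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, transform

__all__ = [
    "SquareImage",
    "SegmentationError",
    "segment_wing",
    "costa_angle",
    "square_compose",
    "to_grayscale",
    "GRAY_WEIGHTS",
]

SQUARE = 512
HALF = SQUARE // 2

# ITU-R 601 luma weights; the common grayscale default.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class SegmentationError(RuntimeError):
    """Automatic wing segmentation failed; supply a manual mask."""


@dataclass
class SquareImage:
    """The standardized 512x512 composite with per-wing masks."""

    pixels: np.ndarray  # (512, 512, 3) in [0, 1]
    fore_mask: np.ndarray  # boolean (512, 512), upper half only
    hind_mask: np.ndarray  # boolean (512, 512), lower half only
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.shape != (SQUARE, SQUARE, 3):
            raise ValueError("composite must be 512x512x3")
        if self.fore_mask[HALF:].any() or self.hind_mask[:HALF].any():
            raise ValueError("fore mask must live in the upper half, hind in the lower")

    @property
    def wing_mask(self) -> np.ndarray:
        return self.fore_mask | self.hind_mask


def segment_wing(image: np.ndarray, background_hint="auto") -> np.ndarray:
    """Mask the wing on a uniform light background.

    The background color is taken from ``background_hint`` (an RGB triple)
    or estimated from the image border; foreground is everything whose
    color distance from the background exceeds an Otsu threshold.  The
    largest connected component is kept and interior holes (hyaline wing
    cells that match the background color) are filled.  Fails when no
    component occupies between 1% and 90% of the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("RGB image required")
    rgb = image[..., :3]
    if isinstance(background_hint, str) and background_hint == "auto":
        border = np.concatenate(
            [rgb[0], rgb[-1], rgb[:, 0], rgb[:, -1]], axis=0
        )
        bg = np.median(border, axis=0)
    else:
        bg = np.asarray(background_hint, dtype=float)
    dist = np.sqrt(((rgb - bg) ** 2).sum(axis=-1))
    thr = filters.threshold_otsu(dist)
    fg = dist > thr
    fg = morphology.closing(fg, morphology.disk(2))
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(mask)
    frac = mask.mean()
    if not 0.01 < frac < 0.90:
        raise SegmentationError(
            f"segmented area is {frac:.1%} of the image (must be 1%-90%); "
            "manual masking required"
        )
    return mask


def costa_angle(mask: np.ndarray, central_fraction: float = 0.8) -> float:
    """Orientation (degrees) of the upper wing margin.

    Least-squares line through the uppermost mask pixel of each column,
    restricted to the central span of columns to keep the wing tip and base
    from dominating the fit.
    """
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size < 2:
        raise ValueError("mask too small to estimate orientation")
    lo = cols[0] + (1 - central_fraction) / 2 * (cols[-1] - cols[0])
    hi = cols[-1] - (1 - central_fraction) / 2 * (cols[-1] - cols[0])
    use = cols[(cols >= lo) & (cols <= hi)]
    tops = np.array([np.flatnonzero(mask[:, c])[0] for c in use], dtype=float)
    slope = np.polyfit(use.astype(float), tops, 1)[0]
    return float(np.degrees(np.arctan(slope)))


def _level_and_scale(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate costa horizontal, crop to the wing, rescale to 512 columns."""
    img = np.asarray(image, dtype=float)[..., :3]
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty wing mask")
    # two passes: the line fit improves once the wing is roughly level
    for _ in range(2):
        ang = costa_angle(m)
        if abs(ang) < 0.05:
            break
        img = transform.rotate(img, ang, resize=True, order=1, mode="constant", cval=0.0)
        m = (
            transform.rotate(
                m.astype(float), ang, resize=True, order=0, mode="constant", cval=0.0
            )
            > 0.5
        )
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    img = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    m = m[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    scale = SQUARE / m.shape[1]
    out_h = max(1, int(round(m.shape[0] * scale)))
    img = transform.resize(img, (out_h, SQUARE), order=1, anti_aliasing=scale < 1)
    m = transform.resize(m.astype(float), (out_h, SQUARE), order=0) > 0.5
    # guarantee the full 512-column span survives nearest-neighbour resize
    m[:, 0] |= m[:, 1]
    m[:, -1] |= m[:, -2]
    return img, m, scale


def square_compose(
    fore: np.ndarray,
    fore_mask: np.ndarray,
    hind: np.ndarray,
    hind_mask: np.ndarray,
    specimen_id: str = "",
) -> SquareImage:
    """Compose leveled, rescaled fore- and hindwings into the 512-px square.

    Each wing is placed flush-left with its top edge at the top of its half
    (forewing upper half, hindwing lower half); everything outside the wing
    masks is exact black.
    """
    pixels = np.zeros((SQUARE, SQUARE, 3))
    masks = {}
    prov: dict = {"specimen_id": specimen_id}
    for name, img, msk, row0 in (
        ("fore", fore, fore_mask, 0),
        ("hind", hind, hind_mask, HALF),
    ):
        wimg, wmask, scale = _level_and_scale(img, msk)
        if wimg.shape[0] > HALF:
            raise ValueError(
                f"{name} wing is {wimg.shape[0]} px tall after rescale (max {HALF}): "
                "aspect ratio violation"
            )
        full = np.zeros((SQUARE, SQUARE), dtype=bool)
        full[row0 : row0 + wmask.shape[0]] = wmask
        region = pixels[row0 : row0 + wimg.shape[0]]
        region[wmask] = np.clip(wimg, 0, 1)[wmask]
        masks[name] = full
        prov[f"{name}_scale"] = scale
        prov[f"{name}_height"] = int(wimg.shape[0])
    return SquareImage(
        pixels=pixels, fore_mask=masks["fore"], hind_mask=masks["hind"], provenance=prov
    )


def to_grayscale(
    square: SquareImage | np.ndarray, weights: tuple[float, float, float] = GRAY_WEIGHTS
) -> np.ndarray:
    """Luminance by a fixed weighted channel sum (default ITU-R 601)."""
    pixels = square.pixels if isinstance(square, SquareImage) else np.asarray(square)
    w = np.asarray(weights, dtype=float)
    return pixels[..., :3] @ (w / w.sum())
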