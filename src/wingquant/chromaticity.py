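"""Hierarchical chromaticity coefficients (63 per specimen).

Each pixel's RGB is mapped to luminance-free chromaticity coordinates
r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B), which removes overall
lighting differences between scans.  The 512-px composite square is then
decomposed into 21 nested sub-images - the whole square, each wing, the
proximal/middle/distal thirds of each wing, and the upper/lower halves of
each third - and the mean chromaticity triple of the wing pixels in every
sub-image is recorded, giving 21 x 3 = 63 coefficients.

Means are taken over per-pixel chromaticities (so each region's triple
sums to exactly 1) and over wing-mask pixels only: the exact-black
composite background is excluded because its chromaticity is undefined.
Regions containing no wing pixels receive the neutral triple (1/3, 1/3,
1/3) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import HALF, SQUARE, SquareImage

__all__ = [
    "ChromaticityVector",
    "to_chromaticity",
    "subimage_regions",
    "region_catalogue",
    "chromaticity_vector",
    "N_REGIONS",
    "DEGENERATE",
]

N_REGIONS = 21
DEGENERATE = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

# Integer column cuts of each wing's 512-px span into thirds.
_THIRD_EDGES = (0, 171, 341, SQUARE)
_THIRD_NAMES = ("proximal", "middle", "distal")


@dataclass
class ChromaticityVector:
    """63 coefficients ordered (region 1..21) x (r, g, b)."""

    values: np.ndarray
    region_names: list[str]
    degenerate: list[str] = field(default_factory=list)
    specimen_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 3 * N_REGIONS:
            raise ValueError("chromaticity vector must have exactly 63 coefficients")


def to_chromaticity(R, G, B):
    """Map channel values to luminance-free chromaticity coordinates.

    Works elementwise on arrays.  The black degenerate case R+G+B=0 maps to
    the neutral triple (1/3, 1/3, 1/3).
    """
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(R < 0) or np.any(G < 0) or np.any(B < 0):
        raise ValueError("channel values must be non-negative")
    total = R + G + B
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, R / total, DEGENERATE[0])
        g = np.where(total > 0, G / total, DEGENERATE[1])
        b = np.where(total > 0, B / total, DEGENERATE[2])
    if r.ndim == 0:
        return float(r), float(g), float(b)
    return r, g, b


def subimage_regions(square: SquareImage | None = None) -> dict[str, np.ndarray]:
    """The 21 hierarchical sub-image masks of the 512-px square.

    Ordered: whole square; fore wing; hind wing; three thirds per wing
    (proximal, middle, distal); anterior/posterior halves of each third.
    The wing "thirds" cut the 512 columns at 171 and 341; the halves split
    each third's rows at the midline of that wing's half of the square.
    """
    regions: dict[str, np.ndarray] = {}
    full = np.ones((SQUARE, SQUARE), dtype=bool)
    regions["whole"] = full
    halves = {"fore": (0, HALF), "hind": (HALF, SQUARE)}
    for wing, (r0, r1) in halves.items():
        m = np.zeros_like(full)
        m[r0:r1] = True
        regions[wing] = m
    for wing, (r0, r1) in halves.items():
        for t, name in enumerate(_THIRD_NAMES):
            m = np.zeros_like(full)
            m[r0:r1, _THIRD_EDGES[t] : _THIRD_EDGES[t + 1]] = True
            regions[f"{wing}_{name}"] = m
    for wing, (r0, r1) in halves.items():
        mid = (r0 + r1) // 2
        for t, name in enumerate(_THIRD_NAMES):
            c0, c1 = _THIRD_EDGES[t], _THIRD_EDGES[t + 1]
            up = np.zeros_like(full)
            up[r0:mid, c0:c1] = True
            lo = np.zeros_like(full)
            lo[mid:r1, c0:c1] = True
            regions[f"{wing}_{name}_upper"] = up
            regions[f"{wing}_{name}_lower"] = lo
    assert len(regions) == N_REGIONS
    return regions


def region_catalogue() -> list[str]:
    """Region names in vector order."""
    return list(subimage_regions().keys())


def chromaticity_vector(
    square: SquareImage, specimen_id: str = "", label: str = ""
) -> ChromaticityVector:
    """Mean per-region chromaticity over wing pixels: 63 coefficients."""
    rgb = square.pixels
    r, g, b = to_chromaticity(rgb[..., 0], rgb[..., 1], rgb[..., 2])
    chroma = np.stack([r, g, b], axis=-1)
    wing = square.wing_mask
    values = []
    names = []
    degenerate = []
    for name, region in subimage_regions().items():
        sel = region & wing
        names.append(name)
        if not sel.any():
            values.extend(DEGENERATE)
            degenerate.append(name)
        else:
            values.extend(chroma[sel].mean(axis=0))
    return ChromaticityVector(
        values=np.array(values),
        region_names=names,
        degenerate=degenerate,
        specimen_id=specimen_id or str(square.provenance.get("specimen_id", "")),
        label=label,
    )
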