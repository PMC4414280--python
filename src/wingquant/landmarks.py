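"""Landmark template, band-collapse protocol, and Procrustes superimposition.

Every wing carries a fixed 50-landmark template: LMs 1-14 are structural
outline/vein points (LM 1 = anterior base corner, LM 7 = apex, LM 14 =
posterior base corner) and LMs 15-50 are band points, six per band for
bands I-VI, each band crossing the six longitudinal reference lines
(anterior edge, four internal veins, posterior edge) in anterior-to-
posterior order.  Band I is the distal-most band (adjacent to the apex),
band VI the proximal-most (adjacent to the wing base).

Wings missing bands, or with bands that do not reach the anterior or
posterior wing edge, are brought onto the shared template by *collapsing*
landmarks:

* the template is split between bands III and IV;
* a missing band among I-III takes the six points of the next existing
  band on the apical side, or all six collapse to LM 7 (the apex) when no
  band exists apically of it;
* a missing band among IV-VI takes the six points of the next existing
  band on the basal side, or - for band VI and any band with no basal
  neighbour - its upper three points collapse to LM 1 and its lower three
  to LM 14;
* a band not reaching the anterior/posterior edge has its uncovered edge
  points moved medially to its intersection with the nearest covered
  reference vein.

Collapsing never invents coordinates: every output point is either a
supplied intersection, another band's point, LM 1, LM 7 or LM 14.

Generalized Procrustes analysis (GPA) removes translation, scale and
rotation (reflections excluded) by iterative least-squares alignment to a
consensus; aligned fore- and hindwing sets concatenate into the
200-coefficient landmark vector per specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkSet",
    "LandmarkVector",
    "collapse_bands",
    "procrustes_align",
    "assemble_vector",
    "mean_shape",
    "band_slice",
]

N_OUTLINE = 14
N_BANDS = 6
POINTS_PER_BAND = 6
N_LANDMARKS = N_OUTLINE + N_BANDS * POINTS_PER_BAND  # 50

# 1-based template landmark numbers of the anchor points (paper-style
# numbering; stored 0-based internally).
LM1, LM7, LM14 = 0, 6, 13


@dataclass
class LandmarkSet:
    """One wing's 50-landmark configuration."""

    coords: np.ndarray  # (50, 2)
    wing: str = "fore"  # "fore" | "hind"
    units: str = "px"  # "px" (raw) | "procrustes" (aligned)
    collapse_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(f"LandmarkSet needs exactly {N_LANDMARKS} 2-D points")

    @property
    def outline(self) -> np.ndarray:
        return self.coords[:N_OUTLINE]

    def band_points(self, band: int) -> np.ndarray:
        """Six points of band ``band`` (0-based index, band I = 0)."""
        return self.coords[band_slice(band)]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centroid_size(self) -> float:
        return float(np.sqrt(((self.coords - self.centroid()) ** 2).sum()))


@dataclass
class LandmarkVector:
    """Concatenated aligned fore+hind coordinates: 200 coefficients."""

    values: np.ndarray
    specimen_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 4 * N_LANDMARKS:
            raise ValueError("landmark vector must have exactly 200 coefficients")


def band_slice(band: int) -> slice:
    """Template slice holding the six points of 0-based band index ``band``."""
    if not 0 <= band < N_BANDS:
        raise ValueError("band index out of range")
    start = N_OUTLINE + band * POINTS_PER_BAND
    return slice(start, start + POINTS_PER_BAND)


def collapse_bands(
    raw_intersections: list,
    presence: list[bool],
    extents: list[tuple[int, int]] | None,
    outline: np.ndarray,
    wing: str = "fore",
) -> LandmarkSet:
    """Apply the band-collapse protocol and assemble a full 50-point set.

    Parameters
    ----------
    raw_intersections:
        Per band (I..VI), either ``None`` (band absent) or a ``(6, 2)`` array
        of band-edge/reference-line intersections in anterior-to-posterior
        order; rows for reference lines outside the band's extent may be NaN.
    presence:
        Six booleans, band present/absent.
    extents:
        Per band, the (first, last) covered reference-line indices (0-based,
        0 = anterior edge, 5 = posterior edge).  ``None`` derives coverage
        from non-NaN rows of the intersections.
    outline:
        The 14 structural outline points (LMs 1-14).
    """
    outline = np.asarray(outline, dtype=float)
    if outline.shape != (N_OUTLINE, 2):
        raise ValueError("outline must contain exactly 14 points")
    if len(raw_intersections) != N_BANDS or len(presence) != N_BANDS:
        raise ValueError("exactly six bands required")

    flags: dict = {}
    band_pts: list[np.ndarray | None] = [None] * N_BANDS

    # Step 1: within-band medial collapse of truncated edge points.
    for b in range(N_BANDS):
        if not presence[b]:
            if raw_intersections[b] is not None and not np.all(
                np.isnan(np.asarray(raw_intersections[b], dtype=float))
            ):
                raise ValueError(f"absent band {b + 1} must not carry intersections")
            continue
        pts = np.asarray(raw_intersections[b], dtype=float)
        if pts.shape != (POINTS_PER_BAND, 2):
            raise ValueError(f"band {b + 1} must supply a (6, 2) intersection array")
        if extents is not None:
            first, last = extents[b]
        else:
            covered = np.flatnonzero(~np.isnan(pts[:, 0]))
            if covered.size == 0:
                raise ValueError(f"band {b + 1} has no covered reference line")
            first, last = int(covered[0]), int(covered[-1])
        if not 0 <= first <= last < POINTS_PER_BAND:
            raise ValueError(f"band {b + 1} has an invalid extent ({first}, {last})")
        if np.any(np.isnan(pts[first : last + 1])):
            raise ValueError(f"band {b + 1} is missing covered intersections")
        out = pts.copy()
        out[:first] = pts[first]  # anterior truncation -> nearest covered vein
        out[last + 1 :] = pts[last]  # posterior truncation
        if first > 0 or last < POINTS_PER_BAND - 1:
            flags[b] = f"truncated->veins[{first},{last}]"
        band_pts[b] = out

    # Step 2: missing bands I-III collapse apically (terminating at LM 7).
    for b in (2, 1, 0):
        if presence[b]:
            continue
        donor = next((d for d in range(b - 1, -1, -1) if presence[d]), None)
        if donor is None:
            band_pts[b] = np.tile(outline[LM7], (POINTS_PER_BAND, 1))
            flags[b] = "collapsed->LM7"
        else:
            band_pts[b] = band_pts[donor].copy()
            flags[b] = f"collapsed->band{donor + 1}"

    # Step 3: missing bands IV-VI collapse basally (terminating at LMs 1/14).
    for b in (3, 4, 5):
        if presence[b]:
            continue
        donor = next((d for d in range(b + 1, N_BANDS) if presence[d]), None)
        if donor is None:
            pts = np.empty((POINTS_PER_BAND, 2))
            pts[:3] = outline[LM1]
            pts[3:] = outline[LM14]
            band_pts[b] = pts
            flags[b] = "collapsed->LM1/LM14"
        else:
            band_pts[b] = band_pts[donor].copy()
            flags[b] = f"collapsed->band{donor + 1}"

    coords = np.vstack([outline] + [band_pts[b] for b in range(N_BANDS)])
    return LandmarkSet(coords=coords, wing=wing, units="px", collapse_flags=flags)


def _normalize(coords: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    c = coords - coords.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size < 1e-12:
        raise ValueError("degenerate landmark set: all points coincident")
    return c / size


def _rotate_onto(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of ``src`` onto ``ref``."""
    u, _, vt = np.linalg.svd(ref.T @ src)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    rot = u @ s @ vt
    return src @ rot.T


def procrustes_align(
    sets: list[LandmarkSet],
    wing: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> list[LandmarkSet]:
    """Generalized Procrustes superimposition of ``sets``.

    Translation to a common centroid, scaling to unit centroid size and
    rotation (reflection excluded) minimizing summed squared distances to an
    iteratively re-estimated consensus; the consensus is initialized from the
    first specimen and iteration stops when the mean shape moves by less
    than ``tol``.
    """
    if len(sets) < 2:
        raise ValueError("GPA needs at least two landmark sets")
    if wing is not None and any(s.wing != wing for s in sets):
        raise ValueError(f"all sets must be {wing} wings")

    shapes = [_normalize(s.coords) for s in sets]
    consensus = shapes[0].copy()
    for _ in range(max_iter):
        shapes = [_rotate_onto(sh, consensus) for sh in shapes]
        new = _normalize(np.mean(shapes, axis=0))
        if np.sqrt(((new - consensus) ** 2).sum()) < tol:
            consensus = new
            break
        consensus = new
    shapes = [_rotate_onto(sh, consensus) for sh in shapes]
    return [
        LandmarkSet(coords=sh, wing=s.wing, units="procrustes", collapse_flags=dict(s.collapse_flags))
        for sh, s in zip(shapes, sets)
    ]


def assemble_vector(
    fore_aligned: LandmarkSet,
    hind_aligned: LandmarkSet,
    specimen_id: str = "",
    label: str = "",
) -> LandmarkVector:
    """Concatenate aligned fore+hind sets as x1,y1..x50,y50 (fore) then hind."""
    for s, w in ((fore_aligned, "fore"), (hind_aligned, "hind")):
        if s.units != "procrustes":
            raise ValueError(f"{w} set must be Procrustes-aligned")
    values = np.concatenate([fore_aligned.coords.ravel(), hind_aligned.coords.ravel()])
    return LandmarkVector(values=values, specimen_id=specimen_id, label=label)


def mean_shape(aligned: list[LandmarkSet], labels: list[str]) -> dict[str, LandmarkSet]:
    """Per-label coordinate-wise mean configuration in Procrustes space."""
    if len(aligned) != len(labels):
        raise ValueError("one label per landmark set required")
    out: dict[str, LandmarkSet] = {}
    for lab in dict.fromkeys(labels):
        group = [s.coords for s, l in zip(aligned, labels) if l == lab]
        if not group:
            raise ValueError(f"empty label group {lab!r}")
        wing = next(s.wing for s, l in zip(aligned, labels) if l == lab)
        out[lab] = LandmarkSet(
            coords=np.mean(group, axis=0), wing=wing, units="procrustes"
        )
    return out
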