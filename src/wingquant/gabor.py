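"""Gabor wavelet transformation (510 pattern coefficients per specimen).

A Gabor wavelet is a sinusoidal carrier under a Gaussian envelope; its
inner product with an image patch responds to oriented light/dark
structure (bands, veins, edges) at the wavelet's scale and position.  The
bank tiles the 512-px square hierarchically with four scales - one
512-px-diameter wavelet, a 2x2 grid of 256-px, 4x4 of 128-px and 8x8 of
64-px (85 placements) - each evaluated at three rotations (0, 120 and
240 degrees) for both the real (even) and imaginary (odd) component:
85 x 3 x 2 = 510 signed coefficients in a fixed (scale desc, row-major
position, rotation asc, real-then-imaginary) order, so every coefficient
maps deterministically back to a wing location.

Parameterization: carrier wavelength = diameter/2 (two cycles across the
support), Gaussian envelope sigma = diameter/4, support truncated at the
stated diameter.  The real component is DC-corrected (exactly zero mean
over its support) so it ignores constant image regions; the odd-symmetric
imaginary component is zero-mean by construction.  Both components are
L2-normalized so coefficient magnitudes are comparable across scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaborWavelet", "GaborBank", "GaborVector", "build_bank", "gwt_vector"]

DEFAULT_SCALES = (512, 256, 128, 64)
DEFAULT_ROTATIONS = (0.0, 120.0, 240.0)


@dataclass(frozen=True)
class GaborWavelet:
    """One bank entry: a windowed wavelet array plus its placement."""

    scale: int  # support diameter in px
    row: int  # placement grid row
    col: int  # placement grid column
    rotation: float  # carrier orientation, degrees
    component: str  # "real" | "imag"
    kernel: np.ndarray  # (scale, scale) array, zero outside circular support

    @property
    def center(self) -> tuple[float, float]:
        """Center (row, col) in image pixel coordinates."""
        return (
            self.row * self.scale + self.scale / 2,
            self.col * self.scale + self.scale / 2,
        )


@dataclass
class GaborBank:
    image_size: int
    scales: tuple[int, ...]
    rotations: tuple[float, ...]
    wavelets: list[GaborWavelet]

    def __len__(self) -> int:
        return len(self.wavelets)


@dataclass
class GaborVector:
    """510 signed coefficients in fixed bank order."""

    values: np.ndarray
    specimen_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def _kernels(
    diameter: int, rotation_deg: float, wavelength: float | None, sigma: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary wavelet arrays on a ``diameter``-sized patch."""
    lam = wavelength if wavelength is not None else diameter / 2
    sig = sigma if sigma is not None else diameter / 4
    c = (diameter - 1) / 2
    y, x = np.mgrid[0:diameter, 0:diameter].astype(float)
    y -= c
    x -= c
    theta = np.radians(rotation_deg)
    u = x * np.cos(theta) + y * np.sin(theta)  # along-carrier axis
    support = (x**2 + y**2) <= (diameter / 2) ** 2
    env = np.exp(-(x**2 + y**2) / (2 * sig**2))
    phase = 2 * np.pi * u / lam
    real = np.where(support, env * np.cos(phase), 0.0)
    imag = np.where(support, env * np.sin(phase), 0.0)
    # DC correction of the even component over its circular support.
    real[support] -= real[support].mean()
    for k in (real, imag):
        norm = np.sqrt((k**2).sum())
        if norm > 0:
            k /= norm
    return real, imag


def build_bank(
    image_size: int = 512,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    rotations: tuple[float, ...] = DEFAULT_ROTATIONS,
    wavelength: float | None = None,
    sigma: float | None = None,
) -> GaborBank:
    """Hierarchically tiled Gabor bank; defaults give 510 coefficients.

    ``wavelength``/``sigma`` override the per-scale defaults (diameter/2 and
    diameter/4) when given as absolute pixel values.
    """
    wavelets: list[GaborWavelet] = []
    for d in scales:
        if d > image_size:
            raise ValueError(f"scale {d} exceeds image size {image_size}")
        if image_size % d:
            raise ValueError(f"scale {d} does not tile a {image_size}-px image")
        n = image_size // d
        for rot in rotations:
            real, imag = _kernels(d, rot, wavelength, sigma)
            for row in range(n):
                for col in range(n):
                    wavelets.append(GaborWavelet(d, row, col, rot, "real", real))
                    wavelets.append(GaborWavelet(d, row, col, rot, "imag", imag))
    # fixed order: scale desc, row-major position, rotation asc, real/imag
    wavelets.sort(
        key=lambda w: (
            -w.scale,
            w.row,
            w.col,
            w.rotation,
            0 if w.component == "real" else 1,
        )
    )
    return GaborBank(
        image_size=image_size, scales=tuple(scales), rotations=tuple(rotations),
        wavelets=wavelets,
    )


def gwt_vector(
    gray: np.ndarray, bank: GaborBank, specimen_id: str = "", label: str = ""
) -> GaborVector:
    """Project a grayscale square onto every bank wavelet (signed inner products)."""
    gray = np.asarray(gray, dtype=float)
    if gray.shape != (bank.image_size, bank.image_size):
        raise ValueError(
            f"image must be {bank.image_size}x{bank.image_size}, got {gray.shape}"
        )
    values = np.empty(len(bank.wavelets))
    for i, w in enumerate(bank.wavelets):
        r0, c0 = w.row * w.scale, w.col * w.scale
        patch = gray[r0 : r0 + w.scale, c0 : c0 + w.scale]
        values[i] = float(np.sum(patch * w.kernel))
    return GaborVector(values=values, specimen_id=specimen_id, label=label)


def bank_catalogue(bank: GaborBank) -> list[dict]:
    """Per-coefficient descriptors (scale, grid position, rotation, component)."""
    return [
        {
            "scale": w.scale,
            "row": w.row,
            "col": w.col,
            "rotation": w.rotation,
            "component": w.component,
        }
        for w in bank.wavelets
    ]
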