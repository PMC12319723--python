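"""Tile extraction, amplitude spectra, spectral stretching and accumulation.

The tilt-corrected periodogram average sums, over all tiles of a tilt
image, the amplitude spectrum of each tile resampled along the frequency
axis by that tile's stretch factor::

    P_corrected(k) = sum_tiles  A_tile(S_tile * k)

so that Thon rings from tiles at different local defocus land on the ring
positions of the defocus at the tilt axis and add coherently.  Samples that
a stretch S > 1 would pull from beyond Nyquist are masked out and tracked
in a per-pixel weight map instead of being zero-filled into the sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ContractViolationError, EmptyResultError, InvalidParameterError
from .geometry import TileSpec
from .lut import ScalingLut, lookup_stretch

__all__ = [
    "PowerSpectrum",
    "extract_tile",
    "amplitude_spectrum",
    "apply_stretch",
    "accumulate",
]


@dataclass
class PowerSpectrum:
    """Accumulated 2-D spectrum with per-pixel accumulation weights.

    ``values`` is the raw sum over tiles; ``weights`` counts how many valid
    (in-band) stretched samples landed on each pixel.  The DC component sits
    at the center pixel (index T//2).  ``mode`` records whether amplitudes
    |F| or powers |F|^2 were summed.
    """

    values: np.ndarray
    weights: np.ndarray
    pixel_size_a: float
    mode: str = "amplitude"

    def __post_init__(self):
        if self.values.shape != self.weights.shape:
            raise InvalidParameterError("values and weights must share a shape")
        if self.mode not in ("amplitude", "power"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def k_step(self) -> float:
        """Frequency increment per pixel, 1/Å."""
        return 1.0 / (self.side * self.pixel_size_a)

    def normalized(self) -> np.ndarray:
        """Per-pixel mean (values / weights); zero where no sample landed."""
        out = np.zeros_like(self.values)
        m = self.weights > 0
        out[m] = self.values[m] / self.weights[m]
        return out


def extract_tile(image: np.ndarray, center_raw_px, tile_size_px: int) -> np.ndarray:
    """Crop a T×T tile around a raw-frame center and subtract its mean.

    ``center_raw_px`` is the absolute pixel position (x, y); it is rounded
    to the nearest integer pixel — tiles are never resampled or rotated.
    """
    t = int(tile_size_px)
    half = t // 2
    ny, nx = image.shape
    cx = int(round(float(center_raw_px[0])))
    cy = int(round(float(center_raw_px[1])))
    if cx - half < 0 or cx + half > nx or cy - half < 0 or cy + half > ny:
        raise ContractViolationError(
            f"tile footprint at ({cx}, {cy}) size {t} leaves the {image.shape} image"
        )
    tile = np.asarray(image[cy - half:cy + half, cx - half:cx + half], dtype=float).copy()
    tile -= tile.mean()
    return tile


def _raised_cosine(t: int) -> np.ndarray:
    w = np.hanning(t)
    return np.outer(w, w)


def amplitude_spectrum(tile: np.ndarray, taper: bool = False) -> np.ndarray:
    """|FFT| of a square tile, DC-centered.

    ``taper`` applies a raised-cosine window before the transform (off by
    default, matching common periodogram practice for CTF work).
    """
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise InvalidParameterError(f"tile must be square 2-D, got {tile.shape}")
    if taper:
        tile = tile * _raised_cosine(tile.shape[0])
    return np.abs(np.fft.fftshift(np.fft.fft2(tile)))


def apply_stretch(spectrum: np.ndarray, stretch: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a DC-centered spectrum: output at k carries the input at S*k.

    Bilinear interpolation about the DC center pixel; the DC sample itself is
    pinned (S*0 = 0).  For S > 1, output pixels whose source frequency S*k
    exceeds Nyquist are flagged invalid in the returned boolean mask rather
    than zero-filled.  S == 1 is an exact identity.
    """
    if stretch <= 0:
        raise InvalidParameterError(f"stretch must be positive, got {stretch}")
    n = spectrum.shape[0]
    c = n // 2
    if stretch == 1.0:
        return spectrum.astype(float, copy=True), np.ones_like(spectrum, dtype=bool)
    idx = np.arange(n, dtype=float)
    src = c + stretch * (idx - c)
    yy = np.broadcast_to(src[:, None], (n, n))
    xx = np.broadcast_to(src[None, :], (n, n))
    out = map_coordinates(np.asarray(spectrum, dtype=float), [yy, xx],
                          order=1, mode="constant", cval=0.0)
    if stretch < 1.0:
        mask = np.ones((n, n), dtype=bool)
    else:
        # invalid where the source radius S*|k| passes Nyquist (c bins)
        dy = src[:, None] - c
        dx = src[None, :] - c
        mask = dy * dy + dx * dx <= float(c) * float(c)
        out[~mask] = 0.0
    return out, mask


def accumulate(tiles: Sequence[TileSpec], image: np.ndarray,
               lut: ScalingLut | None, defocus_at_axis_a: float,
               tile_size_px: int, pixel_size_a: float, mode: str = "amplitude",
               taper: bool = False) -> PowerSpectrum:
    """Tilt-corrected periodogram average over ``tiles`` of a raw image.

    With ``lut=None`` (or zero tilt, where every stretch evaluates to 1)
    this reduces to the plain periodogram average.  Summation is
    order-independent; tiles are processed in the given (deterministic
    grid) order.
    """
    tiles = list(tiles)
    if not tiles:
        raise EmptyResultError("cannot accumulate an empty tile list")
    if mode not in ("amplitude", "power"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if lut is not None:
        lut.check_pixel_size(pixel_size_a)

    ny, nx = image.shape
    cx, cy = nx // 2, ny // 2
    values = weights = None
    for spec in tiles:
        center_abs = (spec.center_raw_px[0] + cx, spec.center_raw_px[1] + cy)
        tile = extract_tile(image, center_abs, tile_size_px)
        spec_amp = amplitude_spectrum(tile, taper=taper)
        if mode == "power":
            spec_amp = spec_amp * spec_amp
        s = 1.0 if lut is None else lookup_stretch(lut, defocus_at_axis_a,
                                                   spec.defocus_offset_a)
        stretched, mask = apply_stretch(spec_amp, s)
        if values is None:
            values = np.zeros_like(stretched)
            weights = np.zeros_like(stretched)
        values += stretched
        weights += mask
    return PowerSpectrum(values=values, weights=weights,
                         pixel_size_a=pixel_size_a, mode=mode)
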