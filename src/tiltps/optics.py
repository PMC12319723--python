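"""Electron-optical constants and the contrast transfer function (CTF) model.

The CTF of a microscope with a spherical objective lens is modelled as a
2-D function of spatial frequency ``k`` (in 1/Å)::

    CTF(k) = -w1 * sin(chi(k)) - w2 * cos(chi(k))
    chi(k) = pi * lambda * k**2 * df  -  (pi/2) * lambda**3 * k**4 * Cs  +  phi

where ``lambda`` is the relativistic electron wavelength, ``df`` the defocus
(positive = underfocus), ``Cs`` the spherical aberration, ``phi`` an optional
phase-plate phase shift, ``w2`` the amplitude-contrast fraction and
``w1 = sqrt(1 - w2**2)`` the phase-contrast fraction.

All spatial quantities are in Å internally: defocus in Å, Cs converted from
mm, frequencies in 1/Å.  Astigmatism is not part of this model (defocus is a
scalar); an anisotropic-defocus evaluation for diagnostics lives in
:mod:`tiltps.ctffit`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "OpticsParams",
    "FrequencyGrid",
    "electron_wavelength",
    "phase_shift_chi",
    "ctf_value",
    "ctf_image",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in Å.

    Parameters
    ----------
    voltage_kv
        Accelerating voltage in kV; must be positive.

    Returns
    -------
    float
        Wavelength in Å; e.g. ~0.0197 Å at 300 kV.
    """
    if voltage_kv <= 0:
        raise InvalidParameterError(f"voltage must be positive, got {voltage_kv} kV")
    v = float(voltage_kv) * 1e3  # volts
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass(frozen=True)
class OpticsParams:
    """Microscope/optics constants feeding the CTF model.

    Attributes
    ----------
    voltage_kv : accelerating voltage in kV.
    cs_mm : spherical aberration Cs in mm.
    amplitude_contrast : w2, dimensionless fraction in [0, 1].
    phase_shift_rad : additional phase shift (phase plate), radians.
    pixel_size_a : pixel size in Å/px.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    phase_shift_rad: float = 0.0
    pixel_size_a: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.amplitude_contrast <= 1.0):
            raise InvalidParameterError(
                f"amplitude_contrast must be in [0, 1], got {self.amplitude_contrast}"
            )
        if self.voltage_kv <= 0:
            raise InvalidParameterError(f"voltage_kv must be > 0, got {self.voltage_kv}")
        if self.cs_mm < 0:
            raise InvalidParameterError(f"cs_mm must be >= 0, got {self.cs_mm}")
        if self.pixel_size_a <= 0:
            raise InvalidParameterError(f"pixel_size_a must be > 0, got {self.pixel_size_a}")

    @property
    def wavelength_a(self) -> float:
        return electron_wavelength(self.voltage_kv)

    @property
    def w2(self) -> float:
        """Amplitude-contrast fraction."""
        return self.amplitude_contrast

    @property
    def w1(self) -> float:
        """Phase-contrast fraction, sqrt(1 - w2^2)."""
        return float(np.sqrt(1.0 - self.amplitude_contrast**2))

    @property
    def cs_a(self) -> float:
        """Spherical aberration in Å."""
        return self.cs_mm * 1e7

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Å for this pixel size."""
        return 1.0 / (2.0 * self.pixel_size_a)


def phase_shift_chi(optics: OpticsParams, k, defocus_a):
    """CTF phase argument chi(k) in radians.

    ``k`` (1/Å) and ``defocus_a`` (Å) broadcast together, so a 2-D frequency
    grid combined with a per-pixel defocus array is allowed.
    """
    k = np.asarray(k, dtype=float)
    lam = optics.wavelength_a
    k2 = k * k
    return (
        np.pi * lam * k2 * np.asarray(defocus_a, dtype=float)
        - 0.5 * np.pi * lam**3 * k2 * k2 * optics.cs_a
        + optics.phase_shift_rad
    )


def ctf_value(optics: OpticsParams, k, defocus_a):
    """Signed CTF, dimensionless in [-1, 1], at frequency ``k`` (1/Å)."""
    chi = phase_shift_chi(optics, k, defocus_a)
    return -optics.w1 * np.sin(chi) - optics.w2 * np.cos(chi)


@dataclass(frozen=True)
class FrequencyGrid:
    """Square grid of spatial-frequency magnitudes with DC at the center.

    For side length ``n`` the DC pixel sits at index ``n // 2`` (the
    quadrant-shifted layout produced by ``np.fft.fftshift``); the grid
    corners reach Nyquist * sqrt(2).
    """

    n: int
    pixel_size_a: float

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError(f"grid side must be >= 2, got {self.n}")
        if self.pixel_size_a <= 0:
            raise InvalidParameterError("pixel_size_a must be > 0")

    @property
    def center(self) -> int:
        return self.n // 2

    @functools.cached_property
    def axis(self) -> np.ndarray:
        """1-D frequency axis (1/Å), DC-centered."""
        return np.fft.fftshift(np.fft.fftfreq(self.n, d=self.pixel_size_a))

    @functools.cached_property
    def values(self) -> np.ndarray:
        """2-D array of |k| in 1/Å."""
        ax = self.axis
        return np.hypot(ax[:, None], ax[None, :])

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size_a)


def ctf_image(optics: OpticsParams, grid: FrequencyGrid, defocus_a) -> np.ndarray:
    """Evaluate the CTF on a 2-D frequency grid.

    ``defocus_a`` may be a scalar or an array broadcastable against the grid
    (the latter is used for anisotropic-defocus diagnostics).  With a scalar
    defocus the result is a function of |k| only and therefore centrosymmetric
    about the DC pixel.
    """
    return ctf_value(optics, grid.values, defocus_a)
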