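"""Tilt-series geometry: defocus offsets and the tiling grid.

Tilt-series alignment rotates and shifts each raw image so that the stage
tilt axis lies along the central Y axis of the aligned frame::

    p_aligned = R(theta) @ p_raw + t

with ``R(theta) = [[cos, -sin], [sin, cos]]``.  All coordinates here are
0-based pixel offsets *relative to the image center pixel* (index ``n // 2``
for even ``n``).

With the tilt axis on the aligned Y axis, a stage tilt ``alpha`` (about Y)
creates a defocus gradient along aligned X, and a residual specimen tilt
``beta`` (about X, from non-eucentric mounting) adds a gradient along
aligned Y::

    df_offset(x, y) = handedness * pixel_size * (x * sin(alpha) + y * sin(beta))

The ``handedness`` sign (+1/-1) captures the convention relating image
coordinates to physical height; the wrong sign inverts the gradient and
makes the downstream spectral correction destructive instead of coherent.

Tiles are extracted from the *raw* image (no resampling), so the tile grid
is laid out in the aligned frame — spacing T/2 along the tilt axis, and
perpendicular to it the spacing shrinks so that adjacent columns differ in
defocus by at most the tolerance ``dz`` — and only the tile *centers* are
mapped back to the raw frame through the inverse alignment transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyResultError, InvalidParameterError

__all__ = [
    "TiltImageGeometry",
    "TilingParams",
    "TileSpec",
    "rotation_matrix",
    "aligned_to_raw",
    "raw_to_aligned",
    "defocus_offset",
    "total_defocus",
    "generate_tile_grid",
]


@dataclass(frozen=True)
class TiltImageGeometry:
    """Per-tilt-image alignment and tilt parameters.

    tilt_axis_angle_deg : in-plane rotation theta placing the tilt axis on the
        aligned image's central Y axis.
    shift_px : alignment shift t (pixels), raw -> aligned.
    tilt_angle_deg : stage tilt alpha about the aligned Y axis.
    x_tilt_deg : residual specimen tilt beta about the aligned X axis.
    handedness : +1 or -1, sign of the defocus gradient.
    """

    tilt_axis_angle_deg: float = 0.0
    shift_px: tuple[float, float] = (0.0, 0.0)
    tilt_angle_deg: float = 0.0
    x_tilt_deg: float = 0.0
    handedness: int = 1

    def __post_init__(self):
        if abs(self.tilt_angle_deg) >= 90.0:
            raise InvalidParameterError(
                f"|tilt_angle_deg| must be < 90, got {self.tilt_angle_deg}"
            )
        if abs(self.x_tilt_deg) >= 90.0:
            raise InvalidParameterError(f"|x_tilt_deg| must be < 90, got {self.x_tilt_deg}")
        if self.handedness not in (1, -1):
            raise InvalidParameterError(f"handedness must be +1 or -1, got {self.handedness}")


@dataclass(frozen=True)
class TilingParams:
    """Tile size T (px, even), defocus tolerance dz (Å) and image size (nx, ny)."""

    tile_size_px: int
    defocus_tolerance_a: float
    image_size_px: tuple[int, int]

    def __post_init__(self):
        t = self.tile_size_px
        if t < 32 or t % 2 != 0:
            raise InvalidParameterError(f"tile size must be even and >= 32, got {t}")
        if self.defocus_tolerance_a <= 0:
            raise InvalidParameterError("defocus tolerance must be > 0")
        nx, ny = self.image_size_px
        if t > min(nx, ny):
            raise InvalidParameterError(
                f"tile size {t} exceeds image size {self.image_size_px}"
            )


@dataclass(frozen=True)
class TileSpec:
    """One tile: center in the aligned and raw frames plus its defocus offset.

    Centers are relative to the image center pixel; ``center_raw_px`` is the
    exact (float) mapped position, extraction rounds to the nearest pixel.
    """

    center_aligned_px: tuple[float, float]
    center_raw_px: tuple[float, float]
    defocus_offset_a: float


def rotation_matrix(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def raw_to_aligned(geom: TiltImageGeometry, point_raw) -> np.ndarray:
    """Forward alignment transform R(theta) @ p + t (center-relative pixels)."""
    r = rotation_matrix(geom.tilt_axis_angle_deg)
    return r @ np.asarray(point_raw, dtype=float) + np.asarray(geom.shift_px, dtype=float)


def aligned_to_raw(geom: TiltImageGeometry, point_aligned) -> np.ndarray:
    """Inverse alignment transform R(-theta) @ (p - t)."""
    r = rotation_matrix(-geom.tilt_axis_angle_deg)
    return r @ (np.asarray(point_aligned, dtype=float) - np.asarray(geom.shift_px, dtype=float))


def defocus_offset(geom: TiltImageGeometry, point_aligned, pixel_size_a: float) -> float:
    """Defocus offset (Å) at an aligned-frame point relative to the tilt axis origin."""
    x, y = (float(v) for v in point_aligned)
    sa = math.sin(math.radians(geom.tilt_angle_deg))
    sb = math.sin(math.radians(geom.x_tilt_deg))
    return geom.handedness * pixel_size_a * (x * sa + y * sb)


def total_defocus(defocus_at_axis_a: float, offset_a: float) -> float:
    """Total defocus df(x, y) = df0 + df_offset(x, y)."""
    return defocus_at_axis_a + offset_a


def perpendicular_spacing_px(geom: TiltImageGeometry, tiling: TilingParams,
                             pixel_size_a: float) -> int:
    """Grid spacing perpendicular to the tilt axis.

    T/2, shrunk so that the defocus step between adjacent columns stays
    below the tolerance dz: min(T/2, floor(dz / (pixel * |sin alpha|))).
    """
    half = tiling.tile_size_px // 2
    sa = abs(math.sin(math.radians(geom.tilt_angle_deg)))
    if sa == 0.0:
        return half
    step = math.floor(tiling.defocus_tolerance_a / (pixel_size_a * sa))
    return max(1, min(half, step))


def generate_tile_grid(geom: TiltImageGeometry, tiling: TilingParams,
                       pixel_size_a: float) -> list[TileSpec]:
    """Lay out tile centers in the aligned frame and map them to the raw frame.

    The grid is centered on the aligned origin (the tilt-axis coincidence
    point).  Spacing is T/2 along the tilt axis (aligned Y) and
    ``perpendicular_spacing_px`` along aligned X.  Tiles whose raw-frame
    footprint leaves the image are dropped.
    """
    t = tiling.tile_size_px
    half = t // 2
    nx, ny = tiling.image_size_px
    cx, cy = nx // 2, ny // 2

    dx = perpendicular_spacing_px(geom, tiling, pixel_size_a)
    dy = half

    # cover the whole (shifted, rotated) image footprint
    reach = 0.5 * math.hypot(nx, ny) + math.hypot(*geom.shift_px)
    imax = int(math.ceil(reach / dx))
    jmax = int(math.ceil(reach / dy))

    rinv = rotation_matrix(-geom.tilt_axis_angle_deg)
    tvec = np.asarray(geom.shift_px, dtype=float)

    tiles: list[TileSpec] = []
    for i in range(-imax, imax + 1):
        for j in range(-jmax, jmax + 1):
            pa = np.array([i * dx, j * dy], dtype=float)
            pr = rinv @ (pa - tvec)
            # absolute raw pixel of the tile center (rounded for extraction)
            ax = int(round(pr[0])) + cx
            ay = int(round(pr[1])) + cy
            if ax - half < 0 or ax + half > nx or ay - half < 0 or ay + half > ny:
                continue
            off = defocus_offset(geom, pa, pixel_size_a)
            tiles.append(
                TileSpec(
                    center_aligned_px=(float(pa[0]), float(pa[1])),
                    center_raw_px=(float(pr[0]), float(pr[1])),
                    defocus_offset_a=off,
                )
            )
    if not tiles:
        raise EmptyResultError(
            "no tile fits inside the raw image after boundary filtering"
        )
    return tiles
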