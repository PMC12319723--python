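"""File formats, record assembly and the per-tilt-image processing chain.

Formats handled here:

* MRC2014 mode-2 (float32) image stacks — a compact reader/writer pair
  covering exactly the subset this pipeline produces and consumes.
* IMOD ``.tlt`` (one tilt angle in degrees per line).
* IMOD ``.xf`` (six numbers per line: A11 A12 A21 A22 DX DY; the linear part
  must be a rotation, the transform maps raw -> aligned coordinates
  relative to the image center).

``run_tilt_ctf`` chains geometry -> LUT lookup -> periodogram accumulation
-> CTF fit for every image of a tilt series.
"""

from __future__ import annotations

import logging
import math
import struct
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ctffit, geometry, periodogram
from .errors import FormatError, InvalidInputError, TiltPsError
from .geometry import TilingParams, TiltImageGeometry
from .lut import ScalingLut
from .optics import OpticsParams

__all__ = [
    "read_mrc", "write_mrc", "read_mrc_stack",
    "read_tlt", "write_tlt", "read_xf", "write_xf",
    "TiltSeriesRecord", "assemble_record",
    "FitConfig", "run_tilt_ctf", "load_config", "configure_logging",
]

logger = logging.getLogger("tiltps.pipeline")

_MRC_HEADER_BYTES = 1024
_MAP_ID = b"MAP "


def write_mrc(path, data: np.ndarray, pixel_size_a: float) -> None:
    """Write a 2-D image or 3-D stack as MRC2014 mode 2 (float32, little-endian)."""
    arr = np.asarray(data, dtype="<f4")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError(f"expected 2-D or 3-D data, got shape {data.shape}")
    nz, ny, nx = arr.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz,          # dimensions
                     2,                   # mode 2 = float32
                     0, 0, 0,             # nxstart..
                     nx, ny, nz)          # sampling grid
    struct.pack_into("<6f", header, 40,
                     nx * pixel_size_a, ny * pixel_size_a, nz * pixel_size_a,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76,
                     float(arr.min()), float(arr.max()), float(arr.mean()))
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = _MAP_ID
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(arr.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data as float32 (nz, ny, nx), pixel size Å)."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if raw[208:212] != _MAP_ID:
        raise FormatError(f"{path}: missing 'MAP ' id in header word 53")
    if mode != 2:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    if min(nx, ny, nz) <= 0:
        raise FormatError(f"{path}: non-positive dimensions ({nx}, {ny}, {nz})")
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    xlen, = struct.unpack_from("<f", raw, 40)
    mx, = struct.unpack_from("<i", raw, 28)
    pixel = xlen / mx if mx > 0 and xlen > 0 else 1.0
    start = _MRC_HEADER_BYTES + nsymbt
    nbytes = nx * ny * nz * 4
    if len(raw) < start + nbytes:
        raise FormatError(
            f"{path}: truncated data block (expected {nbytes} bytes, "
            f"found {len(raw) - start})"
        )
    data = np.frombuffer(raw, dtype="<f4", count=nx * ny * nz, offset=start)
    return data.reshape(nz, ny, nx).copy(), float(pixel)


def read_mrc_stack(path) -> tuple[np.ndarray, float]:
    """Read an MRC stack; 2-D files are promoted to depth-1 stacks."""
    return read_mrc(path)


def read_tlt(path) -> list[float]:
    """IMOD .tlt: one tilt angle (degrees) per non-empty line."""
    angles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                angles.append(float(s))
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: not a number: {s!r}") from err
    if not angles:
        logger.warning("%s: empty tilt-angle file", path)
    return angles


def write_tlt(path, angles) -> None:
    with open(path, "w") as fh:
        for a in angles:
            fh.write(f"{a:16.9f}\n")


def read_xf(path) -> list[tuple[float, tuple[float, float]]]:
    """IMOD .xf: per-line (rotation theta in degrees, shift (dx, dy) px).

    The 2x2 linear part must be a pure rotation; scale or skew beyond 1%
    is rejected because the geometry model only supports rigid alignments.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.split()
            if not s:
                continue
            if len(s) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 numbers, got {len(s)}")
            try:
                a11, a12, a21, a22, dx, dy = (float(v) for v in s)
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: non-numeric entry") from err
            lin = np.array([[a11, a12], [a21, a22]])
            sv = np.linalg.svd(lin, compute_uv=False)
            if np.any(np.abs(sv - 1.0) > 0.01):
                raise FormatError(
                    f"{path}: line {lineno}: linear part is not a rigid rotation "
                    f"(singular values {sv})"
                )
            theta = math.degrees(math.atan2(a21, a11))
            out.append((theta, (dx, dy)))
    return out


def write_xf(path, transforms) -> None:
    """Write (theta_deg, (dx, dy)) records as IMOD .xf rows."""
    with open(path, "w") as fh:
        for theta, (dx, dy) in transforms:
            th = math.radians(theta)
            c, s = math.cos(th), math.sin(th)
            fh.write(f"{c:15.12f}{-s:16.12f}{s:16.12f}{c:16.12f}"
                     f"{dx:14.6f}{dy:14.6f}\n")


@dataclass
class TiltSeriesRecord:
    """A tilt series ready for processing: images plus per-image alignment."""

    stack: np.ndarray
    pixel_size_a: float
    tilt_angles_deg: list[float]
    transforms: list[tuple[float, tuple[float, float]]]
    optics: OpticsParams
    x_tilt_deg: float = 0.0
    handedness: int = 1
    nominal_defocus_a: float | None = None

    def geometry_for(self, index: int) -> TiltImageGeometry:
        theta, shift = self.transforms[index]
        return TiltImageGeometry(
            tilt_axis_angle_deg=theta, shift_px=shift,
            tilt_angle_deg=self.tilt_angles_deg[index],
            x_tilt_deg=self.x_tilt_deg, handedness=self.handedness,
        )

    def __len__(self) -> int:
        return self.stack.shape[0]


def assemble_record(stack: np.ndarray, pixel_size_a: float, tilt_angles_deg,
                    transforms, optics: OpticsParams, x_tilt_deg: float = 0.0,
                    handedness: int = 1,
                    nominal_defocus_a: float | None = None) -> TiltSeriesRecord:
    """Validate .tlt/.xf/stack consistency before any computation."""
    n = stack.shape[0]
    if len(tilt_angles_deg) != n or len(transforms) != n:
        raise InvalidInputError(
            f"inconsistent lengths: stack depth {n}, {len(tilt_angles_deg)} tilt "
            f"angles, {len(transforms)} transforms"
        )
    return TiltSeriesRecord(
        stack=stack, pixel_size_a=pixel_size_a,
        tilt_angles_deg=list(tilt_angles_deg), transforms=list(transforms),
        optics=optics, x_tilt_deg=x_tilt_deg, handedness=handedness,
        nominal_defocus_a=nominal_defocus_a,
    )


@dataclass(frozen=True)
class FitConfig:
    """Knobs for the per-image accumulate + fit chain."""

    search_a: tuple[float, float, float] = ctffit.DEFAULT_SEARCH_A
    band: tuple[float, float] | None = None
    mode: str = "amplitude"
    taper: bool = False
    corrected: bool = True
    second_pass: bool = False
    resolution_threshold: float = ctffit.DEFAULT_RESOLUTION_THRESHOLD


def _working_defocus(record: TiltSeriesRecord, tiling: TilingParams,
                     config: FitConfig) -> float:
    """Defocus used to key the LUT before any per-image fit exists."""
    if record.nominal_defocus_a is not None:
        logger.info("LUT keyed on the nominal defocus %.0f Å", record.nominal_defocus_a)
        return record.nominal_defocus_a
    idx = int(np.argmin(np.abs(record.tilt_angles_deg)))
    logger.info("no nominal defocus given; first-pass uncorrected fit on the "
                "lowest-tilt image (index %d, %.1f deg)", idx,
                record.tilt_angles_deg[idx])
    tiles = geometry.generate_tile_grid(record.geometry_for(idx), tiling,
                                        record.pixel_size_a)
    ps = periodogram.accumulate(tiles, record.stack[idx], None, 0.0,
                                tiling.tile_size_px, record.pixel_size_a,
                                mode=config.mode, taper=config.taper)
    result = ctffit.fit_defocus(ps, record.optics, search=config.search_a,
                                band=config.band)
    logger.info("first-pass defocus estimate: %.0f Å", result.defocus_a)
    return result.defocus_a


def run_tilt_ctf(record: TiltSeriesRecord, tiling: TilingParams,
                 lut: ScalingLut | None, config: FitConfig | None = None,
                 ) -> tuple[list[ctffit.CtfFitResult | None],
                            list[periodogram.PowerSpectrum | None]]:
    """Process every tilt image: grid -> stretches -> accumulation -> fit.

    A failure in one image is logged with its index and processing
    continues; the corresponding result/spectrum slots hold ``None``.
    """
    config = config or FitConfig()
    use_lut = lut if config.corrected else None
    df_work = _working_defocus(record, tiling, config) if use_lut is not None else 0.0

    results: list[ctffit.CtfFitResult | None] = []
    spectra: list[periodogram.PowerSpectrum | None] = []
    failures = []
    for i in range(len(record)):
        try:
            geom = record.geometry_for(i)
            tiles = geometry.generate_tile_grid(geom, tiling, record.pixel_size_a)
            ps = periodogram.accumulate(tiles, record.stack[i], use_lut, df_work,
                                        tiling.tile_size_px, record.pixel_size_a,
                                        mode=config.mode, taper=config.taper)
            result = ctffit.fit_defocus(ps, record.optics, search=config.search_a,
                                        band=config.band)
            if config.second_pass and use_lut is not None:
                ps = periodogram.accumulate(tiles, record.stack[i], use_lut,
                                            result.defocus_a, tiling.tile_size_px,
                                            record.pixel_size_a, mode=config.mode,
                                            taper=config.taper)
                result = ctffit.fit_defocus(ps, record.optics,
                                            search=config.search_a, band=config.band)
            results.append(result)
            spectra.append(ps)
        except TiltPsError as err:
            logger.error("image %d failed: %s", i, err)
            failures.append((i, str(err)))
            results.append(None)
            spectra.append(None)
    if failures:
        logger.warning("%d of %d images failed: %s", len(failures), len(record),
                       [i for i, _ in failures])
    return results, spectra


def load_config(path) -> dict:
    """Read a TOML config file into a flat dict of effective values."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
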