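"""Lookup table of defocus-dependent frequency-stretch factors.

A tile at defocus ``df + d`` has its Thon rings compressed/expanded relative
to a tile at ``df``.  The stretch factor ``S`` is the frequency-axis scaling
that best maps one CTF onto the other in the least-squares sense::

    S = argmin_s  sum_k [ CTF(df + d, s*k) - CTF(df, k) ]^2

When spherical aberration is negligible this has the closed form
``S = sqrt(df / (df + d))`` (equate the quadratic phase terms).  For each
defocus ``df_i`` on a grid, ``S`` is computed over a sweep of offsets ``d``
and summarized by a second-order polynomial with the constant term pinned
at 1::

    S(d) = a * d**2 + b * d + 1

The table of (df_i, a, b) plus fit diagnostics is the LUT; querying it picks
the entry nearest in defocus and evaluates the polynomial at the tile's
defocus offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import FitFailureError, InvalidInputError, InvalidParameterError
from .optics import OpticsParams, ctf_value

__all__ = [
    "LutBuildParams",
    "ScalingLutEntry",
    "ScalingLut",
    "fit_stretch_factor",
    "fit_polynomial",
    "build_lut",
    "lookup_stretch",
]

logger = logging.getLogger("tiltps.lut")

#: number of frequency samples used in the least-squares stretch fit
_N_BAND_SAMPLES = 4096
#: half-widths of the bracketing scans around the closed-form initial
#: stretch; widened progressively when the optimum falls on a scan edge
#: (large Cs mismatch at low defocus moves it off the closed form)
_SCAN_HALF_WIDTHS = (0.02, 0.06, 0.18)
_SCAN_POINTS = 161
_S_BOUNDS = (0.5, 2.0)


@dataclass(frozen=True)
class LutBuildParams:
    """Defocus grid, offset sweep and frequency band for LUT construction.

    Defaults: table from 1 to 7 um in 0.5 um steps, offsets swept over
    ±0.5 um in 0.05 um steps, fit band (0.02, 0.9 * Nyquist) 1/Å.
    """

    defocus_min_a: float = 10_000.0
    defocus_max_a: float = 70_000.0
    defocus_step_a: float = 5_000.0
    fit_range_a: float = 5_000.0
    fit_step_a: float = 500.0
    k_fit_band: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.defocus_min_a < self.defocus_max_a:
            raise InvalidParameterError("defocus_min_a must be < defocus_max_a")
        if min(self.defocus_step_a, self.fit_range_a, self.fit_step_a) <= 0:
            raise InvalidParameterError("all steps and ranges must be > 0")
        if self.k_fit_band is not None:
            lo, hi = self.k_fit_band
            if not (0 <= lo < hi):
                raise InvalidParameterError(f"invalid k band {self.k_fit_band}")

    def band_for(self, optics: OpticsParams) -> tuple[float, float]:
        if self.k_fit_band is not None:
            return self.k_fit_band
        return (0.02, 0.9 * optics.nyquist)

    def defoci(self) -> np.ndarray:
        n = int(round((self.defocus_max_a - self.defocus_min_a) / self.defocus_step_a))
        return self.defocus_min_a + self.defocus_step_a * np.arange(n + 1)

    def offsets(self) -> np.ndarray:
        n = int(round(self.fit_range_a / self.fit_step_a))
        return self.fit_step_a * np.arange(-n, n + 1)


@dataclass(frozen=True)
class ScalingLutEntry:
    """Polynomial stretch model S(d) = a*d^2 + b*d + 1 for one defocus value."""

    defocus_a: float
    coeff_a: float
    coeff_b: float
    mean_ctf_residual: float
    poly_residual: float
    fit_range_a: float
    pixel_size_a: float

    def stretch(self, offset_a: float) -> float:
        return self.coeff_a * offset_a**2 + self.coeff_b * offset_a + 1.0


_TSV_HEADER = "# defocus_a\ta\tb\tmean_ctf_residual\tpoly_residual\tfit_range_a\tpixel_size_a"


@dataclass
class ScalingLut:
    """Sorted collection of :class:`ScalingLutEntry`, keyed by pixel size."""

    entries: list[ScalingLutEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries = sorted(self.entries, key=lambda e: e.defocus_a)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pixel_size_a(self) -> float:
        if not self.entries:
            raise InvalidParameterError("empty LUT has no pixel size")
        return self.entries[0].pixel_size_a

    def nearest_entry(self, defocus_a: float) -> ScalingLutEntry:
        """Entry minimizing |df_i - df|; ties broken toward the smaller defocus."""
        if not self.entries:
            raise InvalidParameterError("cannot query an empty LUT")
        best = self.entries[0]
        best_d = abs(best.defocus_a - defocus_a)
        for e in self.entries[1:]:
            d = abs(e.defocus_a - defocus_a)
            if d < best_d:  # strict: earlier (smaller) entry wins ties
                best, best_d = e, d
        return best

    def check_pixel_size(self, pixel_size_a: float) -> None:
        """Refuse use with a run whose pixel size differs by more than 1%."""
        ref = self.pixel_size_a
        if abs(pixel_size_a - ref) > 0.01 * ref:
            raise InvalidParameterError(
                f"LUT was built for pixel size {ref} Å but the run uses "
                f"{pixel_size_a} Å (>1% mismatch); rebuild the LUT"
            )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_TSV_HEADER + "\n")
            for e in self.entries:
                fields = (e.defocus_a, e.coeff_a, e.coeff_b, e.mean_ctf_residual,
                          e.poly_residual, e.fit_range_a, e.pixel_size_a)
                fh.write("\t".join(format(v, ".17g") for v in fields) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "ScalingLut":
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 7:
                    raise InvalidInputError(
                        f"{path}: line {lineno}: expected 7 columns, got {len(parts)}"
                    )
                vals = [float(p) for p in parts]
                entries.append(ScalingLutEntry(*vals))
        return cls(entries=entries)


def _band_axis(band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if not (0 <= lo < hi):
        raise InvalidParameterError(f"invalid k band {band}")
    return np.linspace(lo, hi, _N_BAND_SAMPLES)


def _stretch_objective(optics, defocus_a, offset_a, k, target, use_power):
    def resid(s):
        model = ctf_value(optics, s * k, defocus_a + offset_a)
        if use_power:
            diff = model * model - target * target
        else:
            diff = model - target
        return float(np.mean(diff * diff))

    return resid


def _fit_stretch_full(optics: OpticsParams, defocus_a: float, offset_a: float,
                      band: tuple[float, float], use_power: bool = False
                      ) -> tuple[float, float]:
    """Return (stretch, mean squared CTF residual)."""
    if defocus_a + offset_a <= 0:
        raise InvalidParameterError(
            f"defocus + offset must stay positive, got {defocus_a} + {offset_a}"
        )
    if offset_a == 0.0:
        return 1.0, 0.0
    k = _band_axis(band)
    target = ctf_value(optics, k, defocus_a)
    s0 = math.sqrt(defocus_a / (defocus_a + offset_a))  # Cs=0 closed form

    # vectorized bracketing scan around the closed-form initial value
    for half_width in _SCAN_HALF_WIDTHS:
        scan = np.linspace(s0 - half_width, s0 + half_width, _SCAN_POINTS)
        scan = np.clip(scan, *_S_BOUNDS)
        model = ctf_value(optics, scan[:, None] * k[None, :], defocus_a + offset_a)
        if use_power:
            diff = model * model - (target * target)[None, :]
        else:
            diff = model - target[None, :]
        costs = np.mean(diff * diff, axis=1)
        ibest = int(np.argmin(costs))
        edge = ibest in (0, len(scan) - 1)
        if not edge or scan[ibest] in _S_BOUNDS:
            break
    if edge and scan[ibest] not in _S_BOUNDS:
        raise FitFailureError(
            "stretch optimizer failed to bracket a minimum",
            diagnostics={"defocus_a": defocus_a, "offset_a": offset_a,
                         "scan_best": float(scan[ibest]), "cost": float(costs[ibest])},
        )
    step = scan[1] - scan[0]
    obj = _stretch_objective(optics, defocus_a, offset_a, k, target, use_power)
    res = minimize_scalar(obj, bounds=(scan[ibest] - step, scan[ibest] + step),
                          method="bounded", options={"xatol": 1e-8})
    if not res.success:
        raise FitFailureError("bounded stretch refinement failed",
                              diagnostics={"defocus_a": defocus_a, "offset_a": offset_a})
    if res.fun <= costs[ibest]:
        return float(res.x), float(res.fun)
    return float(scan[ibest]), float(costs[ibest])


def fit_stretch_factor(optics: OpticsParams, defocus_a: float, offset_a: float,
                       band: tuple[float, float], use_power: bool = False) -> float:
    """Least-squares frequency stretch mapping CTF(df + d) onto CTF(df).

    Signed CTF curves are compared by default; ``use_power=True`` compares
    CTF^2 instead (sensitivity analysis).  Returns 1 exactly at zero offset.
    """
    s, _ = _fit_stretch_full(optics, defocus_a, offset_a, band, use_power)
    return s


def fit_polynomial(offsets, stretches) -> tuple[float, float, float]:
    """Fit S(d) = a*d^2 + b*d + 1 by least squares (constant pinned at 1).

    Returns (a, b, rms_residual_per_point).
    """
    d = np.asarray(offsets, dtype=float)
    s = np.asarray(stretches, dtype=float)
    if d.shape != s.shape or d.ndim != 1:
        raise InvalidInputError("offsets and stretches must be equal-length 1-D")
    if np.unique(d).size < 3:
        raise InvalidInputError("need >= 3 distinct offsets for a quadratic fit")
    design = np.stack([d * d, d], axis=1)
    coef, *_ = np.linalg.lstsq(design, s - 1.0, rcond=None)
    resid = design @ coef - (s - 1.0)
    rms = float(np.sqrt(np.mean(resid * resid)))
    return float(coef[0]), float(coef[1]), rms


def build_lut(optics: OpticsParams, params: LutBuildParams | None = None,
              use_power: bool = False) -> ScalingLut:
    """Build the scaling-factor LUT over the defocus grid in ``params``."""
    params = params or LutBuildParams()
    band = params.band_for(optics)
    offsets = params.offsets()
    entries = []
    for df in params.defoci():
        stretches = np.empty_like(offsets, dtype=float)
        residuals = np.empty_like(offsets, dtype=float)
        for i, d in enumerate(offsets):
            try:
                stretches[i], residuals[i] = _fit_stretch_full(
                    optics, float(df), float(d), band, use_power)
            except FitFailureError as err:
                raise FitFailureError(
                    f"stretch fit failed at defocus {df:.0f} Å, offset {d:.0f} Å",
                    diagnostics=err.diagnostics) from err
        a, b, poly_res = fit_polynomial(offsets, stretches)
        entries.append(ScalingLutEntry(
            defocus_a=float(df), coeff_a=a, coeff_b=b,
            mean_ctf_residual=float(np.mean(residuals)), poly_residual=poly_res,
            fit_range_a=params.fit_range_a, pixel_size_a=optics.pixel_size_a,
        ))
    return ScalingLut(entries=entries)


def lookup_stretch(lut: ScalingLut, defocus_at_axis_a: float, offset_a: float) -> float:
    """Polynomial stretch for a tile: nearest-defocus entry evaluated at ``offset_a``.

    Offsets beyond the entry's fit range are extrapolated with a logged
    warning rather than rejected.
    """
    entry = lut.nearest_entry(defocus_at_axis_a)
    if abs(offset_a) > entry.fit_range_a:
        logger.warning(
            "defocus offset %.0f Å outside the LUT fit range ±%.0f Å "
            "(entry %.0f Å); extrapolating the polynomial",
            offset_a, entry.fit_range_a, entry.defocus_a,
        )
    return entry.stretch(offset_a)
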