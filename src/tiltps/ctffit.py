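"""CTF fitting on (tilt-corrected) periodogram averages.

A self-contained defocus fitter in the spirit of the classic Thon-ring
fitting tools: the 2-D spectrum is reduced to a 1-D rotational average,
a smooth background (moving minimum followed by boxcar smoothing, window
tied to the local Thon-ring period) is removed, and the oscillatory
residual is scored against the model CTF curve by normalized
cross-correlation over an exhaustive defocus scan with local refinement.
A moving-window correlation cutoff provides a "fit resolution": the
highest spatial frequency at which the model still tracks the observed
rings.  An equiphase average (binning by the model's phase argument chi
instead of by radius) is provided as a diagnostic, and an optional
astigmatism refinement extends the scalar defocus to (df1, df2, angle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import FitFailureError, InvalidParameterError
from .optics import OpticsParams, phase_shift_chi
from .periodogram import PowerSpectrum

__all__ = [
    "CtfFitResult",
    "RadialProfile",
    "radial_average",
    "subtract_background",
    "background_window_bins",
    "score_defocus",
    "fit_defocus",
    "fit_resolution",
    "equiphase_average",
    "refine_astigmatism",
    "write_diagnostics",
    "read_diagnostics",
    "plot_fit_panel",
]

logger = logging.getLogger("tiltps.ctffit")

#: default defocus search: 0.5–8 um scanned in 0.01 um steps
DEFAULT_SEARCH_A = (5_000.0, 80_000.0, 100.0)
#: default low-resolution edge of the scoring band, Å
DEFAULT_BAND_LOW_A = 30.0
#: moving-window fit-resolution metric: window length in CTF half-periods
DEFAULT_WINDOW_HALFPERIODS = 5
DEFAULT_RESOLUTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class CtfFitResult:
    """Fitted CTF parameters for one spectrum.

    ``defocus_a`` is the scalar fit; when astigmatism refinement ran,
    ``defocus1_a``/``defocus2_a``/``astig_angle_rad`` hold the elliptical
    model (df1 >= df2, angle of the df1 axis) and ``defocus_a`` their mean.
    """

    defocus_a: float
    cross_correlation: float
    fit_resolution_a: float
    search_range_a: tuple[float, float]
    phase_shift_rad: float = 0.0
    defocus1_a: float | None = None
    defocus2_a: float | None = None
    astig_angle_rad: float | None = None
    mode: str = "amplitude"

    def __post_init__(self):
        lo, hi = self.search_range_a
        if not (lo <= self.defocus_a <= hi):
            raise InvalidParameterError(
                f"fitted defocus {self.defocus_a} outside search range {self.search_range_a}"
            )

    @property
    def astigmatic(self) -> bool:
        return self.defocus1_a is not None and self.defocus2_a is not None


@dataclass
class RadialProfile:
    """Rotational average: per-bin frequency (1/Å), mean value and validity."""

    k: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _radius_bins(n: int) -> np.ndarray:
    c = n // 2
    idx = np.arange(n, dtype=float) - c
    return np.rint(np.hypot(idx[:, None], idx[None, :])).astype(int)


def radial_average(spectrum: PowerSpectrum) -> RadialProfile:
    """Rotationally averaged 1-D profile of the normalized spectrum.

    Bin ``b`` collects pixels whose integer-rounded radius is ``b``; only
    pixels with nonzero accumulation weight contribute, and bins beyond the
    Nyquist radius (the array corners) are dropped.
    """
    n = spectrum.side
    c = n // 2
    rbin = _radius_bins(n)
    norm = spectrum.normalized()
    sel = (rbin <= c) & (spectrum.weights > 0)
    sums = np.bincount(rbin[sel], weights=norm[sel], minlength=c + 1)
    counts = np.bincount(rbin[sel], minlength=c + 1)
    valid = counts > 0
    values = np.where(valid, sums / np.maximum(counts, 1), 0.0)
    k = np.arange(c + 1) * spectrum.k_step
    return RadialProfile(k=k, values=values, valid=valid)


def background_window_bins(optics: OpticsParams, defocus_a: float,
                           k: np.ndarray, k_step: float) -> np.ndarray:
    """Per-bin smoothing window: 1.5x the local CTF zero spacing, in bins.

    The zero spacing follows from the phase derivative
    d(chi)/dk = 2 pi lambda k df - 2 pi lambda^3 k^3 Cs; a half-period of
    chi spans pi / |d(chi)/dk| in frequency.
    """
    lam = optics.wavelength_a
    dchi = np.abs(2 * np.pi * lam * k * defocus_a
                  - 2 * np.pi * lam**3 * k**3 * optics.cs_a)
    with np.errstate(divide="ignore"):
        spacing = np.where(dchi > 0, np.pi / np.maximum(dchi, 1e-30), np.inf)
    w = 1.5 * spacing / k_step
    n = len(k)
    return np.clip(np.nan_to_num(w, posinf=n), 3, max(3, n // 4)).astype(int)


def _moving_apply(x: np.ndarray, window_bins, func) -> np.ndarray:
    n = len(x)
    w = np.broadcast_to(np.asarray(window_bins, dtype=int), (n,))
    out = np.empty(n)
    for i in range(n):
        h = max(1, int(w[i]) // 2)
        out[i] = func(x[max(0, i - h):min(n, i + h + 1)])
    return out


def subtract_background(values: np.ndarray, window_bins=None) -> np.ndarray:
    """Remove the smooth baseline under the Thon-ring oscillation.

    A moving minimum (trough envelope) is boxcar-smoothed and subtracted,
    then the result is recentered by subtracting its own boxcar mean so the
    residual oscillates around zero.  ``window_bins`` may be a scalar or a
    per-bin array (see :func:`background_window_bins`); default n/10.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 16:
        raise InvalidParameterError("profile too short for background subtraction")
    if window_bins is None:
        window_bins = max(5, len(x) // 10)
    env = _moving_apply(x, window_bins, np.min)
    bg = _moving_apply(env, window_bins, np.mean)
    resid = x - bg
    return resid - _moving_apply(resid, window_bins, np.mean)


def _model_curve(optics: OpticsParams, k, defocus_a, mode: str,
                 phase_shift_rad: float | None = None) -> np.ndarray:
    opt = optics if phase_shift_rad is None else replace(
        optics, phase_shift_rad=phase_shift_rad)
    chi = phase_shift_chi(opt, k, defocus_a)
    ctf = -opt.w1 * np.sin(chi) - opt.w2 * np.cos(chi)
    return ctf * ctf if mode == "power" else np.abs(ctf)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def score_defocus(residual: np.ndarray, k: np.ndarray, optics: OpticsParams,
                  defocus_a: float, band: tuple[float, float],
                  mode: str = "amplitude") -> float:
    """Normalized cross-correlation of the residual against the model curve.

    Both curves are zero-meaned over the band, making the score invariant
    to positive affine transforms of the residual.
    """
    sel = (k >= band[0]) & (k <= band[1])
    if not np.any(sel):
        raise InvalidParameterError(f"empty scoring band {band}")
    model = _model_curve(optics, k[sel], defocus_a, mode)
    return _ncc(np.asarray(residual)[sel], model)


def _default_band(optics: OpticsParams) -> tuple[float, float]:
    hi_res = max(5.0, 2.5 * optics.pixel_size_a)
    return (1.0 / DEFAULT_BAND_LOW_A, min(1.0 / hi_res, 0.95 * optics.nyquist))


def _prepared_residual(spectrum: PowerSpectrum, optics: OpticsParams,
                       window_defocus_a: float) -> tuple[RadialProfile, np.ndarray]:
    prof = radial_average(spectrum)
    win = background_window_bins(optics, window_defocus_a, prof.k, spectrum.k_step)
    resid = subtract_background(prof.values, win)
    return prof, resid


def fit_defocus(spectrum: PowerSpectrum, optics: OpticsParams,
                search: tuple[float, float, float] = DEFAULT_SEARCH_A,
                band: tuple[float, float] | None = None,
                fit_phase_shift: bool = False) -> CtfFitResult:
    """Exhaustive defocus scan plus bounded local refinement.

    The spectrum's own ``mode`` selects the model curve (|CTF| for summed
    amplitudes, CTF^2 for summed powers).  With ``fit_phase_shift`` the
    phase-plate shift is grid-searched over 0..pi in 10 deg steps.
    Deterministic for fixed input.
    """
    lo, hi, step = search
    if not (0 < lo < hi) or step <= 0:
        raise FitFailureError(f"degenerate search range {search}")
    band = band or _default_band(optics)
    # window scale from the geometric mean of the search range (no defocus
    # estimate exists yet); only sets the background smoothing length
    prof, resid = _prepared_residual(spectrum, optics, math.sqrt(lo * hi))
    sel = (prof.k >= band[0]) & (prof.k <= band[1]) & prof.valid
    if sel.sum() < 8:
        raise FitFailureError(f"scoring band {band} covers {int(sel.sum())} bins")
    kb, rb = prof.k[sel], resid[sel]

    phase_shifts = [optics.phase_shift_rad]
    if fit_phase_shift:
        phase_shifts = list(np.deg2rad(np.arange(0.0, 180.1, 10.0)))

    defoci = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    best = None  # (score, defocus, phase)
    for phi in phase_shifts:
        chi = phase_shift_chi(replace(optics, phase_shift_rad=phi),
                              kb[None, :], defoci[:, None])
        ctf = -optics.w1 * np.sin(chi) - optics.w2 * np.cos(chi)
        models = ctf * ctf if spectrum.mode == "power" else np.abs(ctf)
        models = models - models.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(models, axis=1)
        r0 = rb - rb.mean()
        rn = np.linalg.norm(r0)
        if rn == 0:
            raise FitFailureError("residual is identically zero in the band")
        scores = models @ r0 / np.where(norms > 0, norms * rn, np.inf)
        i = int(np.argmax(scores))
        if best is None or scores[i] > best[0]:
            best = (float(scores[i]), float(defoci[i]), float(phi))
    score0, df0, phi0 = best

    def neg(d):
        return -score_defocus(rb, kb, replace(optics, phase_shift_rad=phi0),
                              d, (kb[0], kb[-1]), spectrum.mode)

    res = minimize_scalar(neg, bounds=(max(lo, df0 - step), min(hi, df0 + step)),
                          method="bounded", options={"xatol": 0.5})
    if res.success and -res.fun > score0:
        df_fit, cc = float(res.x), float(-res.fun)
    else:
        df_fit, cc = df0, score0

    result = CtfFitResult(defocus_a=df_fit, cross_correlation=cc,
                          fit_resolution_a=2.0 * optics.pixel_size_a,
                          search_range_a=(lo, hi), phase_shift_rad=phi0,
                          mode=spectrum.mode)
    fres = fit_resolution(spectrum, optics, result)
    return replace(result, fit_resolution_a=fres)


def fit_resolution(spectrum: PowerSpectrum, optics: OpticsParams,
                   result: CtfFitResult,
                   window_halfperiods: int = DEFAULT_WINDOW_HALFPERIODS,
                   threshold: float = DEFAULT_RESOLUTION_THRESHOLD,
                   band_low_a: float = DEFAULT_BAND_LOW_A) -> float:
    """Highest resolution (Å) at which the model still tracks the rings.

    Walks windows spanning ``window_halfperiods`` half-periods of the fitted
    chi(k) from the low-frequency band edge toward Nyquist; the first window
    whose residual/model correlation drops below ``threshold`` caps the fit
    resolution at that window's start.  Never reports beyond 2x pixel size.
    """
    opt = replace(optics, phase_shift_rad=result.phase_shift_rad)
    prof, resid = _prepared_residual(spectrum, opt, result.defocus_a)
    chi = phase_shift_chi(opt, prof.k, result.defocus_a)
    model = _model_curve(opt, prof.k, result.defocus_a, result.mode)
    nyq_bin = len(prof.k) - 1
    b0 = int(np.searchsorted(prof.k, 1.0 / band_low_a))
    if b0 >= nyq_bin:
        raise InvalidParameterError("low band edge beyond Nyquist")
    span = window_halfperiods * np.pi
    b = b0
    while True:
        e = int(np.searchsorted(chi, chi[b] + span))
        if e > nyq_bin:
            return 2.0 * optics.pixel_size_a  # tracked all the way to Nyquist
        if e - b < 4:
            e = min(nyq_bin, b + 4)
        c = _ncc(resid[b:e + 1], model[b:e + 1])
        if c < threshold:
            if b == b0:
                logger.warning(
                    "model/residual correlation below %.2f already at the "
                    "low-frequency band edge; reporting %.1f Å", threshold,
                    1.0 / prof.k[b0])
            return max(1.0 / prof.k[b], 2.0 * optics.pixel_size_a)
        # advance one half-period
        nb = int(np.searchsorted(chi, chi[b] + np.pi))
        b = nb if nb > b else b + 1


def _k_of_chi(optics: OpticsParams, chi: np.ndarray, defocus_a: float,
              phase_shift_rad: float) -> np.ndarray:
    """Invert chi(k) for k >= 0 on the rising branch (scalar defocus)."""
    lam = optics.wavelength_a
    rhs = np.asarray(chi, dtype=float) - phase_shift_rad
    bcoef = np.pi * lam * defocus_a
    acoef = 0.5 * np.pi * lam**3 * optics.cs_a
    if acoef == 0:
        u = rhs / bcoef
    else:
        disc = np.maximum(bcoef * bcoef - 4 * acoef * rhs, 0.0)
        u = (bcoef - np.sqrt(disc)) / (2 * acoef)
    return np.sqrt(np.maximum(u, 0.0))


@dataclass
class EquiphaseProfile:
    """1-D profile indexed by the fitted model's phase argument chi."""

    chi: np.ndarray
    values: np.ndarray
    valid: np.ndarray


def equiphase_average(spectrum: PowerSpectrum, optics: OpticsParams,
                      result: CtfFitResult) -> EquiphaseProfile:
    """Average the spectrum over contours of constant fitted chi.

    Without astigmatism chi is a monotone function of |k|, so the contours
    are circles and this reduces exactly to the radial average re-indexed
    by chi.  With an astigmatic fit the contours are elliptical: each pixel
    is assigned the radial bin whose (mean-defocus) chi value its own
    directional chi matches.
    """
    opt = replace(optics, phase_shift_rad=result.phase_shift_rad)
    prof = radial_average(spectrum)
    chi_bins = phase_shift_chi(opt, prof.k, result.defocus_a)
    if not result.astigmatic:
        return EquiphaseProfile(chi=chi_bins, values=prof.values, valid=prof.valid)

    n = spectrum.side
    c = n // 2
    idx = np.arange(n, dtype=float) - c
    dy, dx = idx[:, None], idx[None, :]
    r = np.hypot(dy, dx)
    k2d = r * spectrum.k_step
    phi = np.arctan2(dy, dx)
    dmean = 0.5 * (result.defocus1_a + result.defocus2_a)
    ddiff = 0.5 * (result.defocus1_a - result.defocus2_a)
    dloc = dmean + ddiff * np.cos(2.0 * (phi - result.astig_angle_rad))
    chi_pix = phase_shift_chi(opt, k2d, dloc)
    # effective radius: invert the mean-defocus chi at each pixel's chi value
    k_eff = _k_of_chi(opt, chi_pix, dmean, result.phase_shift_rad)
    rbin = np.rint(k_eff / spectrum.k_step).astype(int)
    norm = spectrum.normalized()
    sel = (rbin <= c) & (spectrum.weights > 0) & (r <= c)
    sums = np.bincount(rbin[sel], weights=norm[sel], minlength=c + 1)
    counts = np.bincount(rbin[sel], minlength=c + 1)
    valid = counts > 0
    values = np.where(valid, sums / np.maximum(counts, 1), 0.0)
    return EquiphaseProfile(chi=chi_bins, values=values, valid=valid)


def refine_astigmatism(spectrum: PowerSpectrum, optics: OpticsParams,
                       result: CtfFitResult,
                       band: tuple[float, float] | None = None,
                       max_astig_a: float = 5_000.0) -> CtfFitResult:
    """Optional 3-parameter (df1, df2, angle) refinement after the scalar fit.

    Maximizes the 2-D normalized correlation between the background-flattened
    spectrum and the elliptical model curve over an annulus band.  The
    spectral stretch applied upstream is isotropic, so astigmatism survives
    it only approximately; this refinement is off by default.
    """
    band = band or _default_band(optics)
    opt = replace(optics, phase_shift_rad=result.phase_shift_rad)
    n = spectrum.side
    c = n // 2
    idx = np.arange(n, dtype=float) - c
    dy, dx = idx[:, None], idx[None, :]
    k2d = np.hypot(dy, dx) * spectrum.k_step
    phi = np.arctan2(dy, dx)
    sel = (k2d >= band[0]) & (k2d <= band[1]) & (spectrum.weights > 0)
    if sel.sum() < 64:
        raise FitFailureError("annulus band too small for astigmatism refinement")
    obs = spectrum.normalized()[sel]
    obs = obs - obs.mean()
    k_sel, phi_sel = k2d[sel], phi[sel]

    def neg(p):
        d1, d2, ang = p
        if d1 < d2 or d2 <= 0 or (d1 - d2) > 2 * max_astig_a:
            return 1.0
        dloc = 0.5 * (d1 + d2) + 0.5 * (d1 - d2) * np.cos(2.0 * (phi_sel - ang))
        chi = phase_shift_chi(opt, k_sel, dloc)
        ctf = -opt.w1 * np.sin(chi) - opt.w2 * np.cos(chi)
        m = ctf * ctf if spectrum.mode == "power" else np.abs(ctf)
        return -_ncc(obs, m)

    best = None
    for ang0 in np.deg2rad([0.0, 45.0, 90.0, 135.0]):
        res = minimize(neg, x0=[result.defocus_a + 200.0, result.defocus_a - 200.0, ang0],
                       method="Nelder-Mead",
                       options={"xatol": 5.0, "fatol": 1e-6, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    d1, d2, ang = best.x
    ang = math.remainder(ang, math.pi)
    return replace(result, defocus1_a=float(d1), defocus2_a=float(d2),
                   astig_angle_rad=float(ang),
                   defocus_a=float(0.5 * (d1 + d2)),
                   cross_correlation=float(-best.fun))


_DIAG_HEADER = (
    "# index  defocus1_a  defocus2_a  astig_angle_deg  phase_shift_rad  "
    "cross_correlation  fit_resolution_a"
)


def write_diagnostics(results: list[CtfFitResult], path) -> None:
    """One line per tilt image, column-compatible with CTFFIND-style output."""
    with open(path, "w") as fh:
        fh.write(_DIAG_HEADER + "\n")
        for i, r in enumerate(results):
            d1 = r.defocus1_a if r.astigmatic else r.defocus_a
            d2 = r.defocus2_a if r.astigmatic else r.defocus_a
            ang = math.degrees(r.astig_angle_rad) if r.astigmatic else 0.0
            fh.write(f"{i}\t{d1:.6f}\t{d2:.6f}\t{ang:.6f}\t"
                     f"{r.phase_shift_rad:.6f}\t{r.cross_correlation:.6f}\t"
                     f"{r.fit_resolution_a:.6f}\n")


def read_diagnostics(path) -> np.ndarray:
    """Parse a diagnostics file back into an (n, 7) float array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split()])
    return np.asarray(rows)


def plot_fit_panel(spectrum: PowerSpectrum, optics: OpticsParams,
                   result: CtfFitResult, path) -> None:
    """Diagnostic panel: observed spectrum (top), fitted model (lower left)
    and the equiphase average (lower right)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = spectrum.side
    c = n // 2
    obs = spectrum.normalized()
    lo, hi = np.percentile(obs[spectrum.weights > 0], [1, 99.5])
    obs = np.clip(obs, lo, hi)
    idx = np.arange(n, dtype=float) - c
    k2d = np.hypot(idx[:, None], idx[None, :]) * spectrum.k_step
    chi = phase_shift_chi(replace(optics, phase_shift_rad=result.phase_shift_rad),
                          k2d, result.defocus_a)
    model = np.abs(-optics.w1 * np.sin(chi) - optics.w2 * np.cos(chi))
    panel = obs.copy()
    panel[c:, :c] = lo + (hi - lo) * model[c:, :c]

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(panel, cmap="gray", origin="lower")
    ax.axhline(c, color="w", lw=0.5)
    ax.set_title(f"df = {result.defocus_a / 1e4:.2f} um  cc = "
                 f"{result.cross_correlation:.3f}  fit res = "
                 f"{result.fit_resolution_a:.1f} Å")
    ax.set_axis_off()
    eq = equiphase_average(spectrum, optics, result)
    inset = ax.inset_axes([0.55, 0.05, 0.42, 0.38])
    inset.plot(eq.chi[eq.valid], eq.values[eq.valid], lw=0.7, color="m")
    inset.set_xticks([])
    inset.set_yticks([])
    inset.set_title("equiphase avg", fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
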