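# Methods

## The model

A micrograph's Fourier amplitudes are modulated by the contrast transfer
function of the objective lens,

    CTF(k) = −w₁ sin χ(k) − w₂ cos χ(k),
    χ(k)   = π λ k² Δf − (π/2) λ³ k⁴ Cs + Δφ,

with the electron wavelength λ from the relativistic de Broglie relation
λ = 12.2639 / √(V + 0.97845·10⁻⁶ V²) Å (V in volts), defocus Δf in Å
(positive = underfocus), spherical aberration Cs (converted from mm),
phase-plate shift Δφ, and amplitude-contrast fraction w₂ with
w₁ = √(1 − w₂²). Astigmatism is deliberately not part of the core model:
the pipeline estimates a scalar Δf₀ at the tilt axis, and the spectral
stretch applied to tiles is isotropic, so astigmatism survives the
averaging only approximately. An optional three-parameter (Δf₁, Δf₂,
angle) refinement exists in the fitter for diagnostics.

## Tilted-specimen geometry

The specimen is assumed planar. Tilt-series alignment supplies, per
image, an in-plane rotation θ (placing the stage tilt axis on the aligned
Y axis) and a shift t, with `p_aligned = R(θ) p_raw + t`. In the aligned
frame the defocus offset of a point (x, y), in Å, is

    Δf_offset(x, y) = h · s · (x sin α + y sin β),

where s is the pixel size, α the stage tilt (about aligned Y — hence a
gradient along aligned X, perpendicular to the tilt axis), β any residual
specimen tilt about aligned X, and h = ±1 the handedness relating image
coordinates to physical height. The sign convention cannot be derived
from the alignment files alone; it is an explicit parameter, and getting
it wrong inverts every stretch and demonstrably destroys the averaged
rings (the package's tests assert exactly that).

Tiles are always extracted from the *raw* image — no rotation or
resampling, which preserves astigmatism orientation and avoids
interpolation artifacts — so only the tile-center grid is mapped through
the inverse transform `R(−θ)(p − t)`. The grid is centered on the aligned
origin (the tilt-axis coincidence point), spaced T/2 along the tilt axis
(denser sampling adds no periodogram signal) and
`min(T/2, ⌊δz / (s·|sin α|)⌋)` perpendicular to it, so adjacent columns
never differ in defocus by more than the tolerance δz. Tiles whose raw
footprint leaves the image are dropped rather than padded.

## The stretch-factor lookup table

A tile at defocus Δf + δ has its rings at frequencies scaled by roughly
√(Δf/(Δf+δ)) relative to a tile at Δf. The exact least-squares stretch

    S(Δf, δ) = argmin_s Σ_k [CTF(Δf+δ, s·k) − CTF(Δf, k)]²

is found by a bracketing scan around the Cs = 0 closed form
√(Δf/(Δf+δ)) followed by bounded scalar minimization (s ∈ [0.5, 2],
converged to 10⁻⁸; the scan widens adaptively because a large Cs at low
defocus moves the optimum off the closed form). Signed CTF curves are
compared; a switch allows CTF² for sensitivity analysis. The comparison
band is (0.02, 0.9·Nyquist) 1/Å sampled at 4096 points — dense enough to
resolve the ring period at 7 μm defocus near the band top.

For each defocus on a grid (default 1–7 μm in 0.5 μm steps) the stretch
is swept over offsets ±0.5 μm in 0.05 μm steps and summarized by a
quadratic with the constant term pinned at unity,

    S(δ) = a δ² + b δ + 1,

fit by linear least squares on S − 1. Each table entry stores the
defocus, a, b, the mean CTF residual of the stretch fits, the polynomial
residual, the fit range and the pixel size; the TSV serialization
round-trips doubles exactly (17 significant digits), and a table is
refused at load time if its pixel size differs from the run's by more
than 1%. Lookup selects the nearest-defocus entry (ties toward the
smaller defocus) and evaluates the polynomial; offsets beyond the fit
range extrapolate with a logged warning.

Choice made here: the tabulated summary is the quadratic in δ exactly as
stored; the known cost is that a quadratic with unit constant cannot
follow √(Δf/(Δf+δ)) at the low-defocus end of the table — at Δf = 1 μm
over |δ| ≤ 0.5 μm the best fit deviates by up to ~2.4%, and nearest-entry
quantization (0.5 μm grid) can add a further ~3% for queries midway
between entries. At 3 μm and above, where tilt series are typically
collected, both effects are below 0.1%. See Limitations.

## Coherent accumulation

Each T×T tile is mean-subtracted (no apodization by default; a
raised-cosine taper is available), transformed, and its DC-centered
amplitude spectrum |F| (or power |F|², by flag) is resampled so the
output at frequency k carries the input at S·k, with bilinear
interpolation about the DC pixel (DC itself is pinned, since S·0 = 0).
S = 1 short-circuits to an exact identity — with zero tilt the corrected
average equals the plain periodogram average bit-for-bit. For S > 1,
output pixels whose source frequency exceeds Nyquist are masked invalid
rather than zero-filled; a per-pixel weight map counts valid
contributions, the stored spectrum is the raw sum, and a normalized view
(sum/weights where weights > 0) is derived for fitting and export. The
sum is order-independent and tiles are processed in deterministic grid
order.

## CTF fitting

The fitter reduces the normalized spectrum to a rotational average
(integer-rounded radius bins up to the Nyquist radius; zero-weight bins
are marked missing), removes the smooth background, and scores defocus
candidates by normalized cross-correlation between the residual and the
model curve (|CTF| for amplitude-mode spectra, CTF² for power mode),
which makes the score invariant to positive affine transforms of the
input. Background subtraction is a moving minimum followed by boxcar
smoothing, both with a per-bin window of 1.5× the local ring spacing
π/|dχ/dk| (clipped to [3, n/4] bins), then a recentering pass so the
residual oscillates about zero; before any defocus is known the window
scale is set from the geometric mean of the search range, which only
affects smoothing length.

The search is an exhaustive scan (default 0.5–8 μm in 0.01 μm steps,
vectorized) followed by bounded refinement within one grid step (0.5 Å
tolerance); the result is deterministic and never worse than the best
grid point. The phase shift is held at the configured value unless a
phase-plate flag enables a 0–180° grid search in 10° steps. The scoring
band defaults to 30 Å → max(5 Å, 2.5·pixel).

"Fit resolution" is operationalized as a moving-window metric: windows
spanning five half-periods of the fitted χ(k) slide from the
low-frequency band edge toward Nyquist in one-half-period steps, and the
first window whose residual/model correlation drops below 0.5 caps the
resolution at that window's start frequency (reported as 1/k, never
better than 2× pixel size; if even the first window fails, the
low-frequency band edge is reported with a warning). This is a stated
stand-in for the fit-quality metrics of established fitters, not a claim
of equivalence to any of them.

The equiphase average bins the spectrum by the fitted model's χ value
instead of by radius. Without astigmatism χ is monotone in |k| and the
operation reduces exactly to the radial average re-indexed by χ; with an
astigmatic fit each pixel's directional χ is inverted through the
mean-defocus χ(k) to an effective radius, which follows the elliptical
rings and restores trough depth that circular averaging smears.

## Synthetic data

The simulator draws white Gaussian noise, partitions the field of view
into strips of constant defocus perpendicular to the defocus gradient
(strip pitch: strip width × pixel size × |gradient|, default 64 px), and
filters the same noise realization by the local CTF per strip, blending
adjacent strips with triangular cross-fade weights that form an exact
partition of unity; a white-noise floor (default 10% of the filtered
signal's variance) is added last. Fixed seeds give bit-identical images,
and the ground truth records every strip's defocus. The default series
scenario is 300 kV, Cs 2.7 mm, 7% amplitude contrast, 1.22 Å/px, 3 μm
underfocus, tilts −60°…+60° in 3° steps.

What the generator emulates is exactly the assumption the method rests
on: local power spectra following a laterally varying CTF over a planar
specimen. It contains no specimen structure, no dose-dependent envelope
decay (an optional Gaussian envelope flag exists), no motion blur,
detector MTF or alignment error. Passing tests therefore demonstrate the
geometric and spectral correctness of the correction and fitting
machinery — not robustness to the full noise physiology of real
lamellae.

## Problem sizes and numerical choices in the tests

The coherence-gain tests use ten 2048² replicates at 60° tilt with 512-px
tiles and δz = 200 Å; recovery tests use twenty 1024² images with
defoci drawn uniformly from 1.5–6 μm at tilts {0°, 40°, 60°}. 512-px
tiles are the default because radial bins of a T-px tile resolve ring
spacing only up to k ≈ T·s/(4λΔf): at 3 μm defocus and 1.22 Å pixels a
256-px tile aliases the rings beyond ~5 Å, which caps any fit-resolution
measurement well short of what the correction achieves. All randomness
is seeded; hypothesis property tests run derandomized.

## Limitations

* The quadratic LUT summary breaks down at the low-defocus end of the
  default table (≲1.5 μm) combined with large offsets (|δ| ≳ 0.25 μm),
  where polynomial and nearest-entry quantization errors reach a few
  percent of S; the direct optimizer (`fit_stretch_factor`) is exact
  there and can be used per-tile at higher cost.
* The defocus gradient is assumed purely linear (planar specimen);
  specimen deformation, thickness and doming are not modelled.
* Oversampling along the perpendicular axis is driven by δz only through
  the stage tilt α; a very large residual X-tilt β would warrant the
  same treatment along the tilt axis, which is not implemented.
* Envelope functions, beam tilt and higher-order aberrations are out of
  scope; the fitter's fit-resolution metric is a local stand-in, and
  astigmatism is only approximately preserved through the isotropic
  stretch.
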