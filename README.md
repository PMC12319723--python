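# tiltps — tilt-corrected periodogram averaging for cryo-ET CTF estimation

Contrast-transfer-function (CTF) estimation fits the model

```
CTF(k) = −w₁ sin χ(k) − w₂ cos χ(k)
χ(k)   = π λ k² Δf − (π/2) λ³ k⁴ Cs + Δφ
```

to the Thon rings of a micrograph's power spectrum, where λ is the electron
wavelength, Δf the defocus, Cs the spherical aberration, Δφ a phase-plate
shift, and w₂ / w₁ = √(1 − w₂²) the amplitude/phase contrast fractions.
For tilt-series data this is hard: a tilted planar specimen has a defocus
gradient `Δf(x, y) = Δf₀ + x sin α + y sin β` across the field of view
(α the stage tilt, β any residual specimen tilt), so a whole-image power
spectrum averages rings at many different defoci and the high-resolution
rings destructively cancel — while patch-based local estimation starves on
the very low per-image dose of tilt series.

`tiltps` resolves this using the tilt-series alignment parameters the user
already has. Each raw tilt image is tiled on a grid laid out in the
aligned frame (spacing T/2 along the tilt axis; perpendicular to it the
spacing shrinks so adjacent tiles differ by at most a defocus tolerance
δz). Every tile's defocus offset follows from the alignment geometry, and
its amplitude spectrum is resampled along the frequency axis by a stretch
factor `S ≈ √(Δf₀ / (Δf₀ + δ))` — precomputed as a per-defocus quadratic
lookup table `S(δ) = aδ² + bδ + 1` — so that all rings land at the
positions of the defocus at the tilt axis. The stretched spectra sum into
one *coherent* periodogram average that uses the entire image, on which a
built-in Thon-ring fitter (radial averaging, background subtraction,
exhaustive defocus scan with local refinement, a moving-window fit
resolution, and an equiphase-average diagnostic) recovers Δf₀. Flipping
the handedness of the defocus gradient reverses the stretches and visibly
destroys the rings, which makes the sign convention easy to validate.

A synthetic-data module simulates tilted noise micrographs (strip-wise
CTF-filtered Gaussian noise with cross-faded strips following any tilt
geometry) and full tilt series with `.tlt`/`.xf`/MRC/truth-table output,
so the whole pipeline is testable without downloading data.

## Worked example

```python
import numpy as np
from tiltps import (OpticsParams, SyntheticSpec, TilingParams, TiltImageGeometry,
                    accumulate, build_lut, fit_defocus, generate_tile_grid,
                    simulate_micrograph)

optics = OpticsParams(voltage_kv=300.0, cs_mm=2.7, amplitude_contrast=0.07,
                      pixel_size_a=1.22)
lut = build_lut(optics)                      # defocus 1-7 um, 0.5 um steps

geom = TiltImageGeometry(tilt_angle_deg=60.0)
spec = SyntheticSpec(image_size_px=2048, optics=optics, geometry=geom,
                     defocus_at_axis_a=30_000.0, seed=7)
image, truth = simulate_micrograph(spec)

tiling = TilingParams(tile_size_px=512, defocus_tolerance_a=200.0,
                      image_size_px=(2048, 2048))
tiles = generate_tile_grid(geom, tiling, optics.pixel_size_a)

for label, table in (("tilt-corrected", lut), ("uncorrected", None)):
    ps = accumulate(tiles, image, table, 30_000.0, 512, optics.pixel_size_a)
    r = fit_defocus(ps, optics)
    print(f"{label:>14}: defocus = {r.defocus_a:.0f} A, "
          f"cc = {r.cross_correlation:.3f}, fit resolution = {r.fit_resolution_a:.2f} A")
```

prints

```
tilt-corrected: defocus = 29965 A, cc = 0.908, fit resolution = 2.75 A
   uncorrected: defocus = 29884 A, cc = 0.762, fit resolution = 6.44 A
```

The simulated micrograph is a 60°-tilted specimen at 3 μm underfocus.
Both routes recover the defocus at the tilt axis well (the low-frequency
rings survive either way), but the tilt-corrected average keeps the model
tracking the observed rings to 2.75 Å, whereas the plain average loses
them below 6.4 Å — the coherence gain that makes high-resolution CTF
fitting of tilted images possible. Running the corrected route with
`TiltImageGeometry(tilt_angle_deg=60.0, handedness=-1)` degrades the fit
resolution to ~9.8 Å, worse than no correction at all.

The same pipeline is scriptable from the shell:

```sh
tiltps simulate --out-dir data --image-size 1024 --defocus-um 3
tiltps lut --out lut.tsv
tiltps run data/synthetic.mrc data/synthetic.tlt data/synthetic.xf \
       --lut-tsv lut.tsv --nominal-defocus-um 3 --out-dir results
```

which writes per-image corrected spectra (MRC), a CTFFIND-style
diagnostics table and per-image fit panels.

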