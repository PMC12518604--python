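# Methods

This note records the models, conventions and numerical choices behind
`mfism`, and what the synthetic tests do and do not demonstrate.

## Coordinates, units, sampling

Physical lengths are micrometres except wavelengths and PSF widths,
which follow field convention in nanometres. Design and optics planes
use a square grid with the origin at the window centre, x increasing
with column index and y decreasing with row index (row 0 is maximal y).
The scan/reconstruction layer works in camera-pixel (row, col)
coordinates with y down the rows; the synthetic microscope renders
directly on that grid, so no orientation conversion is round-tripped
through reconstruction.

The default design/propagation sampling step is 0.2 μm, below the
λ/(2·NA) = 0.349 μm aliasing bound of the 488 nm / NA 0.7 designs;
`single_lens_phase` warns when a supplied grid violates the bound, and
the propagator refuses steps above λ/2, where the
propagating/evanescent split is undefined. The continuous phase is
sampled at pixel centres; meta-atom discretization is out of scope.

## Focal length and lens phase

The multifocal design states NA per *individual* lens profile; the
focal length follows the marginal-ray sine convention
f = (D/2)·√(1−NA²)/NA computed once from the full aperture, and the
laterally shifted sub-profiles reuse it (shifts of tens of μm are small
against the 255–510 μm focal lengths used here). The hyperbolic phase
is evaluated exactly (no paraxial expansion) and wrapped to (−π, π].
Where a coherent sum cancels below 10⁻¹² per profile, arg is undefined;
the phase is set to 0 and the position counted in the map's
`n_tie_broken` diagnostic.

Indices are 0-based; the hybrid split keys on the parity of i+j, the
polarization split on the parities of i and j individually, with LCP
taking (even, even) and (odd, odd). Odd n is legal for hybrid; for the
polarization method it yields unequal channel counts and a warning.
`pitch` always means the nearest-neighbour spacing of the full target
grid; the checkerboard sublattices then have spacing s√2.

## Propagation

The angular-spectrum transfer function is evaluated analytically on the
padded frequency grid, H = exp(i2πz√(1/λ²−f_x²−f_y²)), evanescent
components zeroed. Zero-padding (factor 2 by default) suppresses
wrap-around; a local-frequency band limit (Matsushima-style, keyed to
the padded window) suppresses aliasing of H at long distances. On the
unpadded periodic window the operator is unitary over the propagating
band — power conservation and reciprocity hold to 10⁻⁹ — while with
padding the energy that spreads into the pad region is shed at the
crop, which is bookkeeping rather than absorption. The direct
Rayleigh–Sommerfeld summation (exact first-kind kernel, including the
1/(kr) near-field term) serves as the oracle on ≤128² grids; the two
engines agree to better than 10⁻³ relative L2 on smooth apertured
fields (measured 2–5×10⁻⁵ at pad 4).

Scalar theory only: the published simulations for these designs are
scalar, and the NA 0.7 vectorial error is accepted and documented. The
two polarization channels propagate independently and combine only
through the incoherent intensity sum (ideal geometric-phase efficiency
assumed).

Large designs run in complex64; the 20×20 / 500 μm acceptance-scale
simulation (2530² grid, 5060² padded FFT) takes ≈45 s and <2 GB.

## Quality metrics

Definitions the source experiments leave open are fixed as follows and
are declared, not inferred:

- **SNR** = mean fitted peak amplitude ÷ robust background STD
  (1.4826 × median absolute deviation of intensity outside 1.5-AU disks
  around all expected foci). Robust to residual side lobes.
- **Fit success** = converged AND R² ≥ 0.5 AND both FWHMs within
  [0.3, 3]× the theoretical FWHM AND centre within half the window.
  This mirrors the observed failure mode of heavily random-multiplexed
  foci, which stop looking Gaussian.
- Fit window 2.0 AU square; elliptical axis-aligned Gaussian + offset
  (the simulated foci are axis-symmetric; a rotation term adds fragility
  without information).
- Nearest-neighbour pitch: median distance to the closest detected
  neighbour; detection is non-maximum-suppressed local maxima above a
  relative threshold (default 0.3), centroid-refined to subpixel.

The random-multiplexing peak-scaling property test *records* the
measured law rather than asserting a printed one: the brute-force
propagation oracle gives mean peak ∝ N^(−2.02) across N = 1…16
multiplexed profiles (the coherent (area/N)² argument), and the test
asserts strict decrease with an exponent in (−2.5, −1.5).

## Scan geometry and the synthetic microscope

NS = ⌊s/p⌋ scans per axis, NS² frames, frame k = (ky, kx) shifting the
*illumination* by +(kx·p, ky·p) with sample and camera fixed — frames
are therefore mutually registered and the widefield equivalent is the
plain frame sum. The synthetic fixtures use p = s/NS exactly
(p = 0.1875 μm, NS = 16 at s = 3 μm) so the offsets tile each pitch
cell seamlessly, which is the precondition of the flat-field
seamlessness test; `num_scans` itself keeps the floor arithmetic
(NS(3 μm, 172.5 nm) = 17, 289 frames), and a stage step that does not
divide the pitch leaves a real coverage seam that no reconstruction
convention can remove.

Image formation per frame: (excitation × sample) ⊗ emission PSF, scaled
so the stack's expected maximum equals the photon budget (default peak
1000 counts), plus an offset-independent haze term (the sample blurred
with a 5 μm Gaussian, carrying a stated fraction of total counts), then
Poisson shot noise and Gaussian read noise (STD 2). Point emitters and
filament centre-lines are rendered analytically — excitation evaluated
at the emitter, a unit-integral emission Gaussian stamped at its
subpixel position — because splatting points onto the camera grid
before convolution would add a spurious ~⅙-pixel² variance that biases
sub-resolution FWHM measurements. Extended structures (the flat layer)
form on the grid. Excitation is an ideal Gaussian lattice in fast mode
or a propagated focal-plane intensity resampled onto the camera grid in
full-physics mode; acceptance-level tests use fast mode, an integration
test exercises the full-physics path.

What the fixtures emulate: sub-resolution beads (point responses),
parallel 350-nm-separated filaments (two-point resolution), a uniform
fluorescent layer (seams), and out-of-focus haze. What they do not:
aberrations, depth sectioning/3-D structure, scattering, photobleaching
and camera-pixel integration. Passing tests therefore demonstrate the
correctness of the reconstruction arithmetic and the resolution laws
under matched-Gaussian assumptions, not instrument performance.

The flat-field fixture uses a photon budget of 20 000 with zero read
noise: its ripple statistic measures reconstruction geometry, and at
peak 1000 the interior RMS would be shot-noise-floored near the 2 %
criterion regardless of geometry; a bright uniform slide at high SNR is
the standard flat-field calibration condition.

## Reconstruction

Pinholes are placed on the design lattice shifted by the known offsets
(model mode) or re-centred per frame on the local centre of mass where
the search window carries ≥10 % of the frame maximum, falling back to
the model position for silent foci (detect mode); if fewer than half of
all pinholes across a nonzero stack could be re-centred, detect mode
aborts — detection-driven positioning needs a densely fluorescent
sample. Default pinhole STD 770 nm with patch radius s/2; at those
values the patch edge sits at 1.95σ, a mild truncation (warned below
1.5σ).

Reassignment contracts each patch by exactly 2 about its focus. Because
the canvas pixel is half the camera pixel, a patch pastes
pixel-for-pixel at canvas position r + r_focus; the fractional focus
position becomes a single bilinear subpixel shift per patch (verified
against a per-pixel brute-force oracle to 10⁻⁹). The bilinear split
adds ≤ ¼ canvas-pixel² variance (≈38 nm STD averaged over fractions),
≈3 % on the 154 nm reassigned spot. The weight map accumulates pinhole
weights identically, and normalization divides where weights exceed
10⁻⁶ of their maximum.

Richardson–Lucy deconvolution uses multiplicative updates with
reflective boundaries (the Gaussian blur operator is then symmetric and
mass-conserving, so flux is preserved within 1 %); σ_eff from
m²σ_em² + (1−m)²σ_ex² with m = 0.5, σ_ex/σ_em from the 488/520 nm
diffraction limits at NA 0.5 (211/225 nm), giving σ_eff = 154 nm —
matching the reassigned-spot STD. A kernel below 0.1 px is treated as a
delta (identity).

**Iteration count.** RL with a matched Gaussian kernel does not
converge to a fixed resolution: on an ideal reassigned spot the FWHM
passes the theoretically supported √2 narrowing after ~3 iterations and
keeps shrinking (×3.3 total at 20 iterations). The package default is
therefore **3 iterations**, calibrated once on an ideal Gaussian spot
to the √2 the effective-PSF theory supports — beyond that, apparent
sharpening of isolated points is noise-limited over-restoration. For
*two-point contrast* the situation inverts: the dip between structures
at ~0.7× the widefield FWHM keeps improving well past the early stop
(3 iterations: 4 %; 20 iterations: 29 % on the 350 nm pair). No single
iteration count yields both the factor-2 point resolution and the deep
two-point contrast in this idealized Gaussian setting; the filament
demo therefore also reports a deep operating point (20 iterations, the
conventional choice), and both are printed with the iteration count in
the provenance. Real systems, with aberrated PSFs and higher noise,
blur this distinction — which is why both behaviours are commonly
reported from a single empirical setting there.

## Known limitations

Scalar diffraction at NA 0.7 underestimates vectorial spot broadening
by a few percent (the simulated single-focus FWHM is 342 nm against the
356 nm scalar estimate). The SNR definition depends on the simulated
window size through the background region; it is meaningful for
comparisons within one geometry, not as an absolute photometric
quantity. The synthetic microscope is 2-D; out-of-focus light is a
static haze kernel, not a defocused 3-D PSF. Detection-driven pinhole
placement requires dense fluorescence and falls back or aborts
otherwise.
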