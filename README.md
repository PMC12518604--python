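# mfism

Multifocal metalens design and image-scanning-microscopy (ISM)
reconstruction, with a synthetic microscope for end-to-end validation.

## The problem

Image scanning microscopy doubles the resolution of a confocal
microscope computationally, but scanning a single focus is slow. A
*multifocal* metalens — a flat optic imprinting one designed phase
profile — excites a dense n×n lattice of foci at once, so a full field
of view needs only NS² = ⌊s/p⌋² camera frames (pitch s, scan step p).
The catch is the design: superimposing hundreds of lens profiles into a
single phase mask either makes adjacent foci interfere (coherent
addition) or degrades every focus (random aperture sharing). This
package implements and compares the design strategies, simulates the
resulting focal arrays with scalar diffraction, grades them with the
standard quality statistics, and reconstructs multifocal scans into
super-resolved images. It is written for microscopists and flat-optics
designers who want to prototype such systems entirely in software.

## Models

**Design.** Each focus (i, j) of an n×n grid gets a hyperbolic lens
phase

φ_ij(x, y) = −(2π/λ)(√((x−x_ij)² + (y−y_ij)² + f²) − f),

with x_ij = x₀ + (i−(n−1)/2)s. Four multiplexing strategies combine the
sub-profiles:

- *phase addition*: ψ_A = arg Σ e^{iφ_ij} — interference-prone at small
  pitch;
- *random*: ψ_R = Σ φ_ij·L_ij, where the binary random matrices L_ij
  partition the aperture exactly (Σ L_ij = 1 everywhere) with sparsity
  1/n² — interference-resistant, but the mean focal peak falls as the
  coherent aperture-sharing law (area/N)², i.e. ∝ N⁻²;
- *hybrid*: the focus grid is split into even/odd checkerboard
  sublattices by the parity of i+j (nearest-neighbour spacing s√2 within
  each), each sublattice built by phase addition, the two results merged
  with a single two-mask random partition: ψ_H = ψ_even L₁ + ψ_odd L₂;
- *polarization hybrid*: four sublattices by the parities of i and j;
  LCP carries (even, even)∪(odd, odd) and RCP the complement, so every
  focus's nearest neighbours are mutually incoherent and the pitch can
  shrink further. Unpolarized response is the incoherent sum of the two
  channel intensities.

**Propagation.** Band-limited angular-spectrum propagation (the exact
spectral solution of the first Rayleigh–Sommerfeld integral), with a
direct Rayleigh–Sommerfeld summation as a small-grid oracle. Coherent
intensity is |Σu|²; incoherent is Σ|u|². One Airy unit is 1.22λ/NA; the
diffraction-limited FWHM is 0.51λ/NA.

**Reconstruction.** For each of the NS² frames, a Gaussian *digital
pinhole* (STD 770 nm by default) is applied around every focus; each
pinholed patch is *contracted by 2 about its focus* onto a 2×-upsampled
canvas (pixel reassignment, √2 resolution gain), the canvas is
normalized by the accumulated pinhole weights, and Richardson–Lucy
deconvolution with a Gaussian kernel of STD
σ_eff² = m²σ_em² + (1−m)²σ_ex² (m = 0.5) supplies the second √2.

## Worked example

`examples/ism_reconstruction.py` simulates a 256-frame multifocal scan
of 25 sub-resolution beads (NA 0.5, 488/520 nm, 3 μm pitch, Poisson +
read noise) and reconstructs it:

```
beads_nm30 fixture (25 beads, NA 0.5, 520 nm emission):
  widefield FWHM   : 529 nm
  deconvolved FWHM : 262 nm
  resolution gain  : 2.02x  (theory: 2x)

filaments_350nm fixture (parallel pair, 350 nm apart):
  widefield dip          : -0.07  (unresolved)
  deconvolved dip (deep) : 0.29  (20 RL iterations)

haze_test fixture (beads + 50% out-of-focus background):
  background rejection   : 11.0x
```

The widefield FWHM equals the emission diffraction limit (530 nm); the
reconstructed beads are twice as sharp; a 350 nm filament pair that the
widefield image cannot separate shows a 29 % dip after deep
deconvolution; and the digital pinhole suppresses out-of-focus haze
11-fold. The other examples cover phase design
(`design_multifocal_lens.py`), focal-array grading
(`simulate_focal_array.py`) and the interleaved LCP/RCP lattices
(`polarization_multiplexing.py`).

A thin CLI exposes the same workflows
(`mfism design|simulate|metrics|scan-sim|reconstruct|benchmark|demo`).

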