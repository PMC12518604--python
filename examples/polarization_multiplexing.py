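"""Interleaved LCP/RCP focus lattices from polarization-hybrid multiplexing.

Designs the 12x12, 2-AU-pitch array (NA 0.7, 100 um, 633 nm), then
counts foci under LCP-only illumination (one staggered sub-array) and
under unpolarized light (incoherent LCP+RCP sum: the complete grid).
"""

import numpy as np

from mfism import (Grid, LensDesignSpec, aperture_field, detect_foci,
                   intensity_coherent, intensity_incoherent,
                   polarization_hybrid_multiplexing,
                   propagate_angular_spectrum)

spec = LensDesignSpec.with_pitch_au(
    2.0, wavelength_nm=633.0, numerical_aperture=0.7, diameter_um=100.0,
    foci_per_side=12, method="polarization_hybrid", seed=1)
grid = Grid.for_aperture(spec.diameter_um, step=0.2, margin=2.0)
lcp_phase, rcp_phase = polarization_hybrid_multiplexing(spec, grid, seed=1)

fields = []
for ph in (lcp_phase, rcp_phase):
    u0 = aperture_field(ph)
    u0.values = u0.values.astype(np.complex64)  # halve memory for the FFT
    fields.append(propagate_angular_spectrum(u0, spec.focal_length_um))

lcp_only = intensity_coherent([fields[0]])
unpolarized = intensity_incoherent(fields)

min_sep = spec.pitch_um / 2.0
n_lcp = len(detect_foci(lcp_only, min_sep, threshold_rel=0.3))
n_unpol = len(detect_foci(unpolarized, min_sep, threshold_rel=0.3))

print(f"pitch                    : {spec.pitch_um:.3f} um (2 AU at 633 nm)")
print(f"LCP-only foci            : {n_lcp}   (expected 72, one sub-array)")
print(f"unpolarized foci         : {n_unpol}  (expected 144 = 12 x 12)")
print()
print("Each focus's four nearest neighbours carry the orthogonal circular")
print("polarization, so adjacent foci cannot interfere — this is what lets")
print("the pitch shrink below the interference limit of a single channel.")
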