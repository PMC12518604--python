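"""End-to-end multifocal ISM on the synthetic microscope.

Simulates a complete 256-frame multifocal scan of sub-resolution beads
(and of a 350-nm filament pair), reconstructs it — digital pinholing,
2x pixel reassignment, normalization, Richardson-Lucy deconvolution —
and prints the resolution numbers.
"""

from mfism.workflows import run_ism_demo

beads = run_ism_demo("beads_nm30", seed=1)
print("beads_nm30 fixture (25 beads, NA 0.5, 520 nm emission):")
print(f"  widefield FWHM   : {beads['widefield_fwhm_nm']:.0f} nm")
print(f"  deconvolved FWHM : {beads['deconvolved_fwhm_nm']:.0f} nm")
print(f"  resolution gain  : {beads['fwhm_ratio']:.2f}x  (theory: 2x)")
print()

fil = run_ism_demo("filaments_350nm", seed=1)
print("filaments_350nm fixture (parallel pair, 350 nm apart):")
print(f"  widefield dip          : {fil['dip_widefield']:.2f}  (unresolved)")
print(f"  deconvolved dip (deep) : {fil['dip_deconvolved_deep']:.2f}  "
      f"({fil['deep_iterations']} RL iterations)")
print()

haze = run_ism_demo("haze_test", seed=1)
print("haze_test fixture (beads + 50% out-of-focus background):")
print(f"  background rejection   : {haze['background_rejection_ratio']:.1f}x")
print()
print("Pixel reassignment contracts every pinholed focal spot about its")
print("focus, improving resolution by sqrt(2); the matched Gaussian")
print("deconvolution supplies the second sqrt(2) for a ~2x overall gain,")
print("while the digital pinhole rejects out-of-focus light.")
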