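"""Amide I deconvolution: secondary structure of a free vs adsorbed enzyme.

Builds a noiseless synthetic spectrum pair from the packaged β-galactosidase
band presets (free in D₂O vs adsorbed on TiO₂), runs the full analysis —
flat-baseline subtraction, second-derivative band detection, constrained
multi-Gaussian fit — and prints the secondary-structure compositions and
their comparison.
"""

from amidefit import (
    compare_compositions,
    composition,
    deconvolve,
    make_free_adsorbed_pair,
    subtract_flat_baseline,
)

free, adsorbed = make_free_adsorbed_pair(noise_sigma=0.0, grid_hi=2050.0)

comps = {}
for name, spectrum in [("free", free), ("adsorbed", adsorbed)]:
    fit = deconvolve(subtract_flat_baseline(spectrum))
    comps[name] = composition(fit)
    print(f"\n{name} enzyme (χ² = {fit.chi_square:.2e}):")
    for band in fit.bandset:
        print(
            f"  {band.center:7.1f} cm⁻¹  FWHM {band.fwhm:5.1f}  "
            f"{band.structure_class:<17} {100 * band.area / sum(b.area for b in fit.bandset):5.1f} %"
        )

change = compare_compositions(comps["free"], comps["adsorbed"])
beta = change.relative_change["beta-sheet"]
print(f"\nβ-sheet content: {comps['free']['beta-sheet']:.1f} % → "
      f"{comps['adsorbed']['beta-sheet']:.1f} % ({100 * beta:+.1f} % relative)")
print(f"random-coil content appears at +{change.delta_points['random']:.1f} points")
print("\nAdsorption converts β-sheet into random structure while the "
      "α-helix fraction stays nearly unchanged — the structural signature "
      "of adsorption-induced enzyme deactivation.")
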