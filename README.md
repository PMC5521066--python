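# amidefit

Quantitative analysis of enzyme adsorption on oxide nanoparticle
agglomerates: infrared secondary-structure analysis, adsorption geometry,
and photometric activity — the three measurements that together explain why
an enzyme loses activity when it binds to a nanoparticle surface.

The package is written for spectroscopists and bionano researchers who need
the full chain from raw ATR-IR reflectance data to a secondary-structure
table, and the surrounding bookkeeping (surface coverage, specific
activity) done reproducibly.

## What it computes

**Amide I band deconvolution.** A protein's amide I band (1700–1595 cm⁻¹)
is a superposition of Gaussian components, one per secondary-structure
class. With absorbance A(ν) = −log₁₀(R/R₀) from the ATR reflectances, the
analysis is

1. subtract a horizontal baseline extrapolated from the flat
   2000–1800 cm⁻¹ region,
2. locate band positions as minima of the Savitzky–Golay second derivative
   d²A/dν²,
3. fit A(ν) = Σᵢ aᵢ·exp(−4 ln2 (ν−νᵢ)²/wᵢ²) by bounded least squares
   (χ² minimisation, amplitudes ≥ 0, FWHM ∈ [15, 45] cm⁻¹), and
4. report each class as a percentage of the summed component areas,
   area = a·w·√(π/(4 ln 2)).

The automatic pipeline additionally refines positions within a small
window, adds components at residual maxima under a Bayesian information
criterion (heavily overlapped components — e.g. a random-coil shoulder
10 cm⁻¹ from a β-sheet band — leave no separate derivative minimum), and
polishes to the exact decomposition when the data are effectively
noiseless.

**Adsorption geometry.** For agglomerates of diameter D (porous sphere,
solid fraction φ, density ρ) and an enzyme of hydrodynamic diameter d:
agglomerate mass (π/6)D³φρ, monolayer capacity 4(D/d)², enzymes per
agglomerate from the dispersion mass balance, coverage as a percentage of
the monolayer, and primary-particle specific surface area 6/(ρd).

**Enzymatic activity.** ONP accumulation measured at 420 nm
(ε = 2.13·10⁴ M⁻¹cm⁻¹) is converted through the quench dilution
(0.5 mL aliquot + 0.7 mL carbonate → factor 2.4) to µmol of product in the
reaction mixture; the least-squares slope versus time is the rate, and
specific activity is rate per mg of enzyme (U/mg). Free/adsorbed ratios
quantify adsorption-induced activity loss.

Seeded generators (`amidefit.synthetic`) produce spectra, desorption
series and assay time courses with known ground truth, so the entire
pipeline is testable without instrument data.

## Worked example

```sh
python examples/01_secondary_structure_from_spectra.py
```

analyses a synthetic free/adsorbed β-galactosidase spectrum pair built from
the packaged D₂O band presets and prints

```
free enzyme (χ² = 2.27e-32):
   1606.0 cm⁻¹  FWHM  22.0  inter-beta-sheet    7.0 %
   1634.0 cm⁻¹  FWHM  32.0  beta-sheet         58.0 %
   1655.0 cm⁻¹  FWHM  25.0  alpha-helix        25.0 %
   1675.0 cm⁻¹  FWHM  23.0  turn               10.0 %

adsorbed enzyme (χ² = 1.76e-30):
   1606.0 cm⁻¹  FWHM  22.0  inter-beta-sheet    5.0 %
   1631.0 cm⁻¹  FWHM  34.0  beta-sheet         42.0 %
   1641.0 cm⁻¹  FWHM  27.0  random             17.0 %
   1659.0 cm⁻¹  FWHM  26.0  alpha-helix        27.0 %
   1677.0 cm⁻¹  FWHM  23.0  turn                9.0 %

β-sheet content: 58.0 % → 42.0 % (-27.6 % relative)
random-coil content appears at +17.0 points
```

— every fitted position, width and area fraction matches the generating
preset: upon adsorption roughly a quarter of the β-sheet content converts
into random structure while the α-helix fraction barely moves. The other
examples cover the coverage geometry (capacity ≈ 151.5 → "≈150" molecules
per agglomerate, assay loading ≈ 6 molecules ≈ 4 % of a monolayer,
SSA ≈ 121 m²/g), the activity assay (4.8 U/mg for a 0.024 µmol/min rate
over 5 µg enzyme) and the phosphate-desorption series.

The same operations are scriptable from the shell:

```sh
amidefit demo --out demo_out          # one-command synthetic reproduction
amidefit coverage                     # geometry report as JSON
amidefit simulate pair --out fixtures # CSV spectrum fixtures
amidefit structure-report --free fixtures/free.csv --adsorbed fixtures/adsorbed.csv
```

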