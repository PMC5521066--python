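# Methods

## Spectral model

All spectra are decadic absorbances A(ν) = −log₁₀(R/R₀) on a strictly
monotonic wavenumber grid (stored ascending; files written back in their
original order). The amide envelope is modelled as a sum of Gaussian
components

A(ν) = Σᵢ aᵢ · exp(−4 ln2 · (ν − νᵢ)² / wᵢ²),

with center νᵢ (cm⁻¹), FWHM wᵢ (cm⁻¹) and amplitude aᵢ (AU); the
integrated area of a component is aᵢ·wᵢ·√(π/(4 ln 2)). Secondary-structure
classes are assigned from νᵢ using the standard D₂O amide I correlation
ranges (1600–1615 inter-molecular β-sheet, 1615–1638 β-sheet, 1639–1648
random coil, 1649–1665 α-helix, 1666–1685 turn); bands in 1480–1595 cm⁻¹
are amide II and never enter composition percentages. In H₂O the α-helix
and random-coil components overlap near 1655 cm⁻¹ and cannot be separated;
the H₂O table therefore reports a merged class (labelled alpha-helix) and
quantitative composition work defaults to D₂O.

## Preprocessing

**Baseline.** A horizontal baseline equal to the mean absorbance over the
flat 2000–1800 cm⁻¹ window is subtracted. For a truly flat window the mean
coincides with any extrapolated horizontal line and is robust to noise.

**Second derivative.** d²A/dν² is computed by Savitzky–Golay local
polynomial fits. Defaults: 9-point window, 5th-order polynomial (≈16 cm⁻¹
at the default 2 cm⁻¹ grid spacing). This choice is deliberate: the
envelope of four overlapping amide I components leaves only shallow
derivative minima for weak shoulder bands, and wider or lower-order
windows (e.g. 13-point cubic) smooth the 1606 and 1675 cm⁻¹ features of a
β-galactosidase-like profile into the main β-sheet minimum entirely. Even
with the exact analytic derivative, composite-band overlap shifts minima
by up to ~3 cm⁻¹ from the true component positions — which motivates the
bounded center refinement below. Non-uniform grids are linearly resampled
to the median spacing (with a warning) before differentiation.

**Band positions.** Local minima of the negative part of d² inside the
search region, filtered by a relative depth threshold (default 5 % of the
deepest minimum); ties at adjacent equal points break toward higher
wavenumber.

## Fitting

`fit_bands` is the classical constrained protocol: band positions are
supplied (typically second-derivative minima) and never varied; amplitudes
are bounded ≥ 0; FWHMs are either fitted inside [15, 45] cm⁻¹ or frozen.
χ² = Σ(data − model)² is minimised by scipy's bounded trust-region
reflective least-squares algorithm (the bounded variant of
Levenberg–Marquardt) with an analytic Jacobian. Convergence is declared at
a relative χ² change below 1e-10 or parameter change below 1e-8 within the
iteration budget; a non-convergent fit is returned flagged, with a
warning.

`deconvolve` is the automatic pipeline for a bare spectrum and differs in
three respects, each forced by properties of overlapped envelopes:

1. **Bounded center refinement.** Detected positions seed the fit but may
   move within ±3 cm⁻¹ (configurable). Pinning centers at the
   overlap-shifted derivative minima propagates the 2–3 cm⁻¹ position bias
   into area-fraction errors of tens of points.
2. **Residual-driven band addition.** Strongly overlapped components can
   leave *no* derivative extremum at all (a random-coil band 10 cm⁻¹ from
   a 34 cm⁻¹-wide β-sheet band is pure shoulder). Candidate bands are
   added at the maximum positive residual (only positive residuals are
   repairable under the aᵢ ≥ 0 constraint) and accepted when the Bayesian
   information criterion, BIC = N·ln(χ²/N) + 3k·ln N for k bands, drops by
   more than 10. The BIC guards against fitting noise: at finite
   signal-to-noise an extra Gaussian must buy a decisive χ² reduction.
3. **Exact-regime polish.** When the measured noise floor (below) is under
   10⁻⁴ of the peak absorbance, the data pin the decomposition and the
   global χ² minimum is essentially zero; 24 seeded jittered restarts with
   free centers escape the near-degenerate local minima that greedy
   addition can land in. A restart is accepted only if it at least halves
   the best χ², so the polish cannot wander at a noise floor. On noiseless
   synthetic data this recovers generating parameters to machine precision
   (χ² ~ 1e-30), including shoulder components with no derivative
   signature.

Vanishing components (area < 0.3 % of the total) are pruned and the fit
repeated. The noise floor is estimated from fourth differences,
σ̂² = E[(Δ⁴y)²]/70, which is blind to smooth band profiles sampled at a
few points per FWHM. Detection escalates through wider smoothing windows
(9→13→17→21→25 points) until the propagated derivative noise is below 5 %
of the deepest minimum, and discards minima shallower than 3× that noise.

**Identifiability caveat.** Blind deconvolution of heavily overlapped
Gaussians is ill-posed under noise: at ~1 % noise-to-peak a two-component
fit of a four-component envelope is statistically adequate, and free-center
fits return badly scattered class areas. This is a property of the problem,
not the optimiser. For noisy data the supported protocol is the classical
one — fix positions (and, across conditions, widths) from the
second-derivative analysis or an established band table, and fit
amplitudes; with positions and widths fixed, area fractions are recovered
to fractions of a percentage point at 0.5 % noise.

## Composition and comparison

Class percentages are 100 × (class area)/(total area) over bands inside
the amide I window (1595–1700 cm⁻¹); they sum to 100 within 0.1. The
comparison report gives per-class differences in percentage points and
relative changes (undefined, not zero, for classes absent from the
reference). A β-sheet relative change between −35 % and −25 % is flagged
as consistent with a "roughly 30 %" reduction.

## Adsorption geometry

Agglomerates are treated as porous spheres: mass m = (π/6)D³φρ with
diameter D, solid fraction φ (default 0.5) and crystal density ρ (default
anatase, 3.8 g·cm⁻³ — the value consistent with the quoted 121 m²/g for
13 nm particles; handbook values span 3.78–3.90, so it is configurable).
The monolayer capacity divides the outer sphere surface 4πR² by the
enzyme's unpacked circular footprint π(d/2)²: capacity = 4(D/d)². An
unpacked footprint reproduces the quoted ≈150 molecules for D = 80 nm,
d = 13 nm; hexagonal close packing (×0.9069) would give ≈137 and is not
used. The load per agglomerate is (enzyme molecules per mL)/(agglomerates
per mL) under verified complete adsorption; adsorption to vessel walls is
neglected. Coverage is load/capacity in percent, with loads above 100 %
flagged as multilayer. SSA = 6/(ρd) assumes dense monodisperse spheres.
Headline rounding (capacity to tens, loads to integers, coverage to whole
percent) matches how such estimates are quoted; unrounded values are
always retained.

## Activity assay

Cuvette ONP concentration follows Beer–Lambert, c = A/(ε·l) with
ε(420 nm) = 2.13·10⁴ M⁻¹cm⁻¹ (alkaline pH after the carbonate quench) and
a default 1 cm path (unstated in typical protocols; configurable). The
quench dilutes the withdrawn aliquot by (V_aliquot + V_stop)/V_aliquot =
2.4 for the default 0.5 + 0.7 mL volumes; whether a given literature value
already includes this factor is often ambiguous, so the correction is
toggleable (`apply_stop_dilution`). Product amount in the reaction mixture
is c × dilution × reaction volume; the rate is the ordinary least-squares
slope over all provided time points (an initial-rate cutoff is available
via `--max-time`), and specific activity is rate/enzyme mass in U/mg.
Reaction volume and enzyme mass per assay are inherently
protocol-specific; defaults (10 mL, 5 µg) are plausible bench values and
all fixtures parameterize them.

## Synthetic data

Generators are deterministic functions of (parameters, seed), using
numpy's seeded `default_rng`. Noise is i.i.d. Gaussian in absorbance — the
simplest model consistent with many-scan-averaged ATR data. Generated
amide spectra default to a total amide I area of 10 AU·cm⁻¹ (free-preset
peak ≈ 0.19 AU, a realistic ATR film absorbance), a 1900–1300 cm⁻¹ grid at
2 cm⁻¹ spacing (extended to 2050 cm⁻¹ where the flat-baseline window is
exercised). The free/adsorbed pair generator equalises total amide I area
so that only composition, not apparent concentration, differs. The
desorption series applies a free retention-fraction schedule to the amide
bands plus a growing 1080 cm⁻¹ phosphate band — it demonstrates, but does
not model, the binding competition. What the generators do **not** emulate:
H₂O/D₂O exchange dynamics, the wavelength dependence of ATR penetration
depth, scattering baselines, non-Gaussian band shapes, and correlated
detector noise. Green tests therefore certify the analysis chain on data
satisfying its model assumptions, not performance on arbitrary instrument
data.

## Numerical choices

- Gaussian evaluation and Jacobian are fully vectorised; fits on ~100-point
  regions take milliseconds.
- The automatic pipeline uses stopping tolerances of 1e-13 (ftol/xtol);
  the looser fit_bands contract (1e-10/1e-8) is insufficient to separate
  near-degenerate decompositions on noiseless data.
- Fixed positions are implemented as center bounds collapsed to ±1e-12,
  so reported centers can differ from the request at that level.
- Degenerate inputs raise: empty band sets, zero spectra, windows with no
  grid points, enzyme larger than agglomerate, more than one band per
  three grid points.

## Known limitations

- Gaussian profiles only (no Lorentzian/Voigt), no Fourier
  self-deconvolution, no absolute protein quantification from intensity.
- The H₂O preset is approximate (two dominant positions only) and marked
  synthetic; D₂O is the quantitative mode.
- The blind pipeline's exact recovery is a noiseless-regime property; see
  the identifiability caveat above.
- Adsorption isotherms, agglomerate fractal structure, and buffer
  equilibria are out of scope; the geometry is a first-order porous-sphere
  model.
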