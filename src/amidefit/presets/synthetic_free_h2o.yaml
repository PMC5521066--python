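# SYNTHETIC approximate H2O-solution preset. Only the two dominant component
# positions (~1630 beta-sheet, ~1655 merged alpha-helix/random) are known for
# the H2O environment; widths and areas here are plausible stand-ins, NOT a
# published parameter table. Quantitative composition work should use the D2O
# presets, where the alpha-helix/random overlap is lifted.
label: synthetic-free-h2o
solvent: H2O
bands:
  - {center: 1630.0, fwhm: 34.0, area_percent: 60.0, structure_class: beta-sheet}
  - {center: 1655.0, fwhm: 28.0, area_percent: 30.0, structure_class: alpha-helix}
  - {center: 1675.0, fwhm: 23.0, area_percent: 10.0, structure_class: turn}
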