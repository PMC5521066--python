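# Amide I component parameters for beta-galactosidase adsorbed on TiO2, in D2O
# (deconvolution reference: five Gaussian components, relative areas in %;
# the 1641 cm-1 random-structure component is absent in the free state)
label: adsorbed-d2o
solvent: D2O
bands:
  - {center: 1606.0, fwhm: 22.0, area_percent: 5.0, structure_class: inter-beta-sheet}
  - {center: 1631.0, fwhm: 34.0, area_percent: 42.0, structure_class: beta-sheet}
  - {center: 1641.0, fwhm: 27.0, area_percent: 17.0, structure_class: random}
  - {center: 1659.0, fwhm: 26.0, area_percent: 27.0, structure_class: alpha-helix}
  - {center: 1677.0, fwhm: 23.0, area_percent: 9.0, structure_class: turn}
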