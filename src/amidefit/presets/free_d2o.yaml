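# Amide I component parameters for free beta-galactosidase in D2O
# (deconvolution reference: four Gaussian components, relative areas in %)
label: free-d2o
solvent: D2O
bands:
  - {center: 1606.0, fwhm: 22.0, area_percent: 7.0, structure_class: inter-beta-sheet}
  - {center: 1634.0, fwhm: 32.0, area_percent: 58.0, structure_class: beta-sheet}
  - {center: 1655.0, fwhm: 25.0, area_percent: 25.0, structure_class: alpha-helix}
  - {center: 1675.0, fwhm: 23.0, area_percent: 10.0, structure_class: turn}
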