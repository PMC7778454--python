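# Decadic molar extinction coefficients of hemoglobin, cm^-1 / (mol/L).
# Values from the compilation by S. Prahl (Oregon Medical Laser Center,
# https://omlc.org/spectra/hemoglobin/), based on data of W. B. Gratzer
# and N. Kollias.
extinction:
  750:
    HbO: 518.0
    Hb: 1405.24
  850:
    HbO: 1058.0
    Hb: 691.32
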