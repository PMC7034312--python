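# Molar extinction coefficients of oxy- and deoxy-hemoglobin at the two laser
# wavelengths, in 1/(M*cm) on the NATURAL-log scale (standard base-10 compiled
# values multiplied by ln 10). The Beer-Lambert inversion in nirsnet.preprocess
# assumes optical density defined with the natural logarithm; swap in a base-10
# table here if you change that convention.
wavelength_nm	eps_hbo	eps_hbr
690	635.51	4724.89
830	2242.72	1595.80
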