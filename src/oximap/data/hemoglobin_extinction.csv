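# Hemoglobin extinction coefficients, mm^-1 per mM, ln(10) basis.
# Converted from the standard compiled molar extinction spectra
# (cm^-1 / M) via eps[mm^-1 mM^-1] = 2.302585e-4 * eps[cm^-1 M^-1].
# Replace this file to use a different compilation.
wavelength_nm,epsilon_oxy,epsilon_deoxy
659,0.07368,0.74294
691,0.06355,0.47248
731,0.08980,0.25379
851,0.24361,0.15918
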