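# Specific extinction coefficients of human oxy- and deoxyhaemoglobin.
# Source: compiled in-vitro molar extinction spectra of haemoglobin
# (S. Prahl, Oregon Medical Laser Center compilation, 1999; after
# W.B. Gratzer and N. Kollias), converted from cm^-1 M^-1 to cm^-1 uM^-1
# (divide by 1e6) and subsampled to the near-infrared window.
# Values are linearly interpolated to the requested wavelength at runtime.
# The table is user-replaceable: any CSV with these columns is accepted.
wavelength_nm,eps_o2hb_cm1_uM1,eps_hhb_cm1_uM1
740,4.46e-4,1.1159e-3
750,5.18e-4,1.4052e-3
760,5.86e-4,1.5485e-3
770,6.50e-4,1.3119e-3
780,7.10e-4,1.1022e-3
800,8.16e-4,7.6170e-4
820,9.16e-4,6.9313e-4
840,1.022e-3,6.9243e-4
850,1.058e-3,6.9132e-4
860,1.092e-3,7.1410e-4
880,1.154e-3,7.2643e-4
900,1.198e-3,7.3080e-4
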