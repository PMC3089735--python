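# Age-dependent differential pathlength factor DPF(age) = a + b * age^c.
# Coefficients for 690, 744, 807 and 832 nm from A. Duncan et al.,
# "Measurement of cranial optical path length as a function of age using
# phase resolved near infrared spectroscopy", Pediatr. Res. 39 (1996).
# The 764 nm and 859 nm rows are linearly interpolated/extrapolated from
# the published coefficient sets (764: between 744 and 807 nm; 859: from
# the 807-832 nm trend) to cover the instrument wavelengths used here.
# The table is user-replaceable: any CSV with these columns is accepted.
wavelength_nm,a,b,c,source
690,5.38,0.049,0.877,duncan1996
744,5.11,0.106,0.723,duncan1996
764,5.072,0.0936,0.752,interpolated
807,4.99,0.067,0.814,duncan1996
832,4.67,0.062,0.819,duncan1996
859,4.324,0.0566,0.824,extrapolated
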