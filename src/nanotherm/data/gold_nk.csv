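# Gold complex refractive index, visible-NIR.
# APPROXIMATE default table: coarse smoothed values after Johnson & Christy,
# Phys. Rev. B 6, 4370 (1972). Intended as an exploratory default only;
# supply your own table (wavelength_nm,n,k CSV) for quantitative work.
wavelength_nm,n,k
400,1.47,1.95
450,1.40,1.88
500,0.97,1.87
520,0.62,2.08
550,0.43,2.46
600,0.25,2.99
650,0.17,3.44
700,0.16,3.81
750,0.17,4.25
800,0.16,4.91
900,0.21,5.66
1000,0.26,6.47
1064,0.27,6.97
1100,0.29,7.26
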