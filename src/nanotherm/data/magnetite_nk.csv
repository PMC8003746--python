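# Magnetite (Fe3O4) complex refractive index, visible-NIR.
# APPROXIMATE default table: coarse values after Schlegel, Alvarado & Wachter,
# J. Phys. C 12, 1157 (1979). Intended as an exploratory default only;
# supply your own table (wavelength_nm,n,k CSV) for quantitative work.
wavelength_nm,n,k
400,2.30,0.70
500,2.35,0.55
600,2.40,0.45
700,2.40,0.35
800,2.38,0.30
900,2.36,0.25
1000,2.35,0.20
1100,2.34,0.18
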