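# Default chemical species for pure-water radiolysis.
# Diffusion coefficients: room-temperature literature values as compiled in the
# standard radiation-chemistry tables (Buxton et al. 1988; Elliot 1994; and the
# parameter sets shipped with common track-chemistry Monte Carlo codes).
# columns: name	charge	diffusion_coefficient_m2_s
name	charge	diffusion_coefficient_m2_s
e_aq	-1	4.90e-9
OH	0	2.30e-9
H	0	7.00e-9
H2	0	4.80e-9
H2O2	0	2.30e-9
H3O+	1	9.46e-9
OH-	-1	5.30e-9
HO2	0	2.00e-9
O2-	-1	1.75e-9
O2	0	2.40e-9
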