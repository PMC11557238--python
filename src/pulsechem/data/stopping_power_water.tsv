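# Electron collision stopping power in liquid water (density 1 g/cm3).
# Coarse table for spur spacing only: ESTAR-like values above 1 keV,
# dielectric-model-informed values below. Log-log interpolation between nodes.
# columns: energy_eV	stopping_power_eV_per_m
energy_eV	stopping_power_eV_per_m
1.0e2	2.20e10
1.5e2	2.45e10
2.0e2	2.40e10
3.0e2	2.20e10
5.0e2	1.85e10
7.0e2	1.55e10
1.0e3	1.26e10
2.0e3	7.90e9
3.0e3	6.00e9
5.0e3	4.27e9
7.0e3	3.36e9
1.0e4	2.26e9
2.0e4	1.32e9
3.0e4	9.70e8
5.0e4	6.60e8
7.0e4	5.30e8
1.0e5	4.12e8
2.0e5	2.80e8
3.0e5	2.36e8
5.0e5	2.03e8
7.0e5	1.92e8
1.0e6	1.85e8
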