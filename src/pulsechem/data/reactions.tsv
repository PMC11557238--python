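# Default reaction set for pure-water radiolysis (no dissolved solutes).
# Rate constants: room-temperature compilation values (Buxton et al. 1988;
# Elliot 1994). For identical-reactant channels (A + A) the tabulated value is
# the OBSERVED-LOSS coefficient, i.e. -d[A]/dt = k [A]^2; the engine divides by
# two once when deriving the pair-encounter effective radius.
# Products: semicolon-separated; implicit H2O on either side is allowed and the
# loader balances H/O with it. Empty product list means "water only".
# unit: M-1s-1 (dm3 mol-1 s-1, bimolecular) or s-1 (first order).
# The O2 rows are inert unless a fixed dissolved-O2 concentration is configured,
# in which case they are converted to pseudo-first-order scavenging channels.
# columns: reactant1	reactant2	products	rate_constant	unit
reactant1	reactant2	products	rate_constant	unit
e_aq	e_aq	H2;OH-;OH-	1.10e10	M-1s-1
e_aq	OH	OH-	3.00e10	M-1s-1
e_aq	H	H2;OH-	2.50e10	M-1s-1
e_aq	H3O+	H	2.30e10	M-1s-1
e_aq	H2O2	OH;OH-	1.10e10	M-1s-1
OH	OH	H2O2	1.10e10	M-1s-1
OH	H		1.55e10	M-1s-1
H	H	H2	1.55e10	M-1s-1
H3O+	OH-		1.43e11	M-1s-1
OH	H2O2	HO2	2.70e7	M-1s-1
OH	H2	H	4.20e7	M-1s-1
H	H2O2	OH	9.00e7	M-1s-1
HO2	OH-	O2-	1.00e10	M-1s-1
OH	O2-	O2;OH-	8.00e9	M-1s-1
OH	HO2	O2	6.00e9	M-1s-1
e_aq	O2	O2-	1.90e10	M-1s-1
H	O2	HO2	2.10e10	M-1s-1
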