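species	phase	charge	dGf_kJ_mol	dHf_kJ_mol	source
acetate	aqueous	-1	-369.32	-486.01	Shock & Helgeson 1990 (aqueous acetate ion, 25 C, 1 bar)
propionate	aqueous	-1	-363.08	-510.75	Shock & Helgeson 1990 (aqueous propanoate ion, 25 C, 1 bar)
H+	proton	1	0.0	0.0	Hanselmann 1991 (conventional standard state)
H2	gas	0	0.0	0.0	Hanselmann 1991 (element reference state)
CO2	gas	0	-394.359	-393.509	Hanselmann 1991
H2O	liquid-water	0	-237.178	-285.840	Hanselmann 1991
CH4	gas	0	-50.75	-74.80	Hanselmann 1991
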