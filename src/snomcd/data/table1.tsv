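# Illustrative S-NOM-CD surface speciation tableau: a theoretical system with
# solely protons as aqueous species and FeOH, HNOM and S0 surface components.
# FeNOMH logK is NOM-material dependent; the shipped value is the humic-acid
# default of the package configuration.
[components]
name	kind	charge	site_density
FeOH	surface_site	-0.5	3.45
HNOM	surface_component	-1
S0	surface_component	0
H	aqueous_master	1
[species]
complex	FeOH	HNOM	S0	H	dz0	dz1	dz2	logK
FeOH	1	0	0	0	0	0	0	0
FeOH2	1	0	0	1	1	0	0	9.3
FeNOM	1	1	0	0	1.5	-1	-0.5	0
FeNOMH	1	1	0	1	1.5	-0.5	0	5
FeOH2-NOM	1	1	0	0	2	-1.5	-0.5	0.6
S-FeOH	1	0	1	0	0	0	0	0
S-FeOH2	1	0	1	1	1	0	0	9.3
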