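# pistilmet element constants, v1
# symbol	monoisotopic_mass_da	nominal_mass	valence	a1_ratio_percent
# monoisotopic_mass_da: mass of the most abundant isotope (CODATA/NIST).
# a1_ratio_percent: (A+1)/A isotopologue intensity contribution per atom, in
# percent. Carbon is fixed at the 1.08 %/C convention used for carbon counting
# from isotopologue ratios (natural 13C/12C is 1.0816 %).
H	1.00782503207	1	1	0.0115
C	12.0	12	4	1.08
N	14.0030740048	14	3	0.3654
O	15.9949146196	16	2	0.0381
P	30.97376163	31	3	0.0
S	31.97207100	32	2	0.7896
Na	22.9897692809	23	1	0.0
K	38.96370668	39	1	0.0125
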