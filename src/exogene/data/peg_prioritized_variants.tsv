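gene	variant	populations	p_value	gene_composite
EP300	p.Asp2412Glu	European	8.40E-21	0.497
EP300	p.Asn251Ser	European	2.98E-02	0.497
HDAC6	p.Gly844Arg	European	7.30E-22	0.259
HDAC6	p.Leu508Ser	European	5.34E-05	0.259
HTT	p.Asp758Asn	European	2.30E-40	0.235
HTT	p.Arg3109His	European	1.38E-17	0.235
CTSD	p.Ile198Val	Hispanic	5.40E-13	0.230
ACP2	p.Thr358Ile	European	1.26E-06	0.229
PRKN	p.Pro37Leu	European	4.59E-02	0.229
FBXO7	p.Asp516His	Hispanic	1.76E-04	0.207
FBXO7	p.Val485Ile	European	1.71E-02	0.207
APP	p.Glu665Lys	European	7.18E-21	0.166
MAPT	p.Thr30Ile	European	9.77E-04	0.160
MAPT	p.Lys293Arg	European	2.29E-03	0.160
ATG4C	p.Thr452Met	European	7.90E-10	0.130
HIP1R	p.Arg613Gln	European	4.44E-23	0.124
HIP1R	p.Arg586Trp	European	2.32E-07	0.124
GNPTAB	p.Met1175Ile	European	2.78E-14	0.111
GBA1	p.Arg78Cys	Hispanic	8.43E-31	0.110
LAMP1	p.Thr189Ser	European;Hispanic	8.29E-06;4.12E-02	0.105
LAMP1	p.Ile309Thr	European	7.91E-03	0.105
SMPD1	p.Arg497Leu	European	1.96E-07	0.088
PINK1	p.Ala383Thr	Hispanic	1.10E-04	0.076
BLOC1S1	p.Asp68Asn	European	4.36E-02	0.074
MCCC1	p.Glu717Lys	European	1.89E-05	0.073
BAG6	p.Pro429Leu	European	7.72E-88	0.063
BAG6	p.Glu293Lys	European	8.78E-04	0.063
GAK	p.Ile413Val	Hispanic	4.40E-03	0.062
GAK	p.Arg654Gln	European	3.44E-02	0.062
GALC	p.Ile144Leufs*27	European	6.21E-09	0.056
GALC	p.Thr112Ala	European	6.04E-03	0.056
NPC1	p.Ile787Val	European	2.63E-02	0.055
ACMSD	p.Lys134Glu	European	3.36E-02	0.049
MCOLN1	p.Ala164Thr	European	2.17E-03	0.047
TSC1	p.Gly984Ser	European	7.49E-04	0.046
LAMP3	p.Ala267Thr	European	5.36E-10	0.036
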