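gene	rfs_p	rfs_hr	os_z	cell_types
PDGFD	0.000002	1.55	5.53	MESO,CAF
FSTL1	0.036424	1.20	5.09	ADI,MESO,CAF
IGFBP6	0.014975	1.25	4.91	MESO,CAF
THBS2	0.000001	1.57	4.59	CAF
FGF1	0.000002	1.51	4.43	MESO
WNT11	0.010436	1.25	4.42	ADI
CXCL12	0.000010	1.51	4.39	ADI,CAF
ANGPTL2	0.001481	1.32	4.36	ADI,MESO
CXCL14	0.000903	1.36	4.29	ADI,MESO,CAF
SPARC	0.000069	1.45	4.19	ADI,MESO,CAF
SEMA3C	0.001502	1.31	3.91	ADI,MESO,CAF
SFRP4	0.020009	1.25	3.90	ADI,MESO,CAF
FSTL3	0.001730	1.32	3.75	ADI,MESO,CAF
FST	0.000115	1.41	3.67	ADI,MESO,CAF
ADIPOQ	0.000028	1.43	3.62	ADI
THBS1	0.000169	1.41	3.57	ADI,MESO
VEGFC	0.011139	1.26	3.56	ADI,MESO,CAF
ANGPT1	0.001125	1.36	3.28	ADI
SLIT3	0.000265	1.41	3.23	ADI,MESO,CAF
IGF1	0.000002	1.51	3.18	ADI
EFEMP1	0.009509	1.27	3.07	ADI,MESO,CAF
GREM1	0.000165	1.38	3.05	ADI,CAF
BMP2	0.007972	1.27	3.03	ADI,MESO,CAF
SEMA5A	0.002967	1.29	2.96	MESO,CAF
OGN	0.004469	1.30	2.80	MESO
INHBA	0.000117	1.43	2.54	CAF
IGFBP5	0.020092	1.22	2.42	ADI,MESO,CAF
TGFB3	0.002885	1.32	2.36	ADI,MESO,CAF
EFNB3	0.049981	1.20	2.32	MESO
EFNA5	0.010729	1.28	2.21	ADI,MESO,CAF
SFRP1	0.021237	1.26	2.03	ADI
BDNF	0.004150	0.75	-3.02	CAF
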