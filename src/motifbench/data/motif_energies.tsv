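# Reference interaction energies (kcal/mol) for the 49-motif library.
# dE_gas: gas-phase interaction energy at the composite coupled-cluster/CBS
# level (supramolecular, counterpoise-corrected).  dE_deh: dehydration free
# energy of complex formation from a continuum solvation model.
# dE_aq = dE_gas + dE_deh (thermodynamic cycle); printed one-decimal values.
motif_no	mode	pdb_id	pair	dE_gas	dE_deh	dE_aq
1	CH-pi	1H1Q	2A6...A31	-1.9	0.5	-1.4
2	CH-pi	4BDB	ODO...L354	-2.2	0.4	-1.8
3	CH-pi	2BTS	U32...I10	-2.4	0.8	-1.6
4	CH-pi	2XIY	XIY...L174	-2.3	0.3	-2.0
5	CH-pi	1UU9	BI3...L88	-3.6	0.3	-3.3
6	CH-pi	2IO6	330...I374	-0.7	0.0	-0.7
7	CH-pi	4GUE	QCT...L147	-3.4	0.7	-2.7
8	CH-pi	3OOG	YTP...A70	-1.9	0.7	-1.2
9	CH-pi	4FKO	20K...I10	-2.3	0.0	-2.3
10	CH-pi	3QL8	X01...L134	-2.5	0.0	-2.5
11	CH-pi	4RC2	3O8...L174	-2.1	0.2	-1.9
12	CH-pi	4RC3	3OA...A56	-1.0	-1.0	-2.0
13	CH-pi	3QX4	X4B...L134	-1.0	0.1	-0.9
14	pi-pi	2V7O	DRN...F90	-1.3	0.0	-1.3
15	pi-pi	3I4B	Z48...Y134	-1.0	0.3	-0.7
16	pi-pi	4DGO	0JW...F113	-4.4	1.6	-2.8
17	pi-pi	3QQF	X07...F82	-2.4	0.7	-1.7
18	pi-pi	3B2T	M33...Y566	-2.0	0.5	-1.5
19	pi-pi	3R6X	X84...F82	-1.9	0.4	-1.5
20	pi-pi	4WG4	UWB...Y131	-0.6	0.3	-0.3
21	pi-pi	1PXN	CK6...F82	-0.7	0.6	-0.1
22	pi-pi	3ROY	22Z...F82	-2.4	0.6	-1.8
23	pi-pi	2C6O	4SP...F82	-1.1	0.8	-0.3
24	pi-pi	3RAK	03Z...F82	-1.7	0.1	-1.6
25	pi-pi	4EL9	AFE...F79	-1.9	0.4	-1.5
26	cation-pi	1PXL	CK4...K33	-6.5	5.3	-1.2
27	cation-pi	1FGI	SU1...K514	-4.4	2.5	-1.9
28	cation-pi	1M2Q	MNX...K68	-2.0	-0.3	-2.3
29	cation-pi	2VGP	AD6...K180	-1.5	1.0	-0.5
30	cation-pi	3OWP	2SB...K72	-9.2	4.5	-4.7
31	cation-pi	3SQQ	99Z...K33	-2.1	0.8	-1.3
32	cation-pi	3RJC	06Z...K33	-2.1	0.5	-1.6
33	cation-pi	3QTW	X3A...K89	-8.4	8.6	0.2
34	H-bond	3SW4	18K...L83	-6.0	4.8	-1.2
35	H-bond	3ZLY	YSO...M146	-4.9	3.7	-1.2
36	H-bond	3RZB	02Z...L83	-7.0	5.2	-1.8
37	H-bond	3RPY	27Z...L83	-7.0	4.4	-2.6
38	H-bond	3R28	XA0...L83	-4.8	4.0	-0.8
39	H-bond	3QZI	X72...L83	-4.6	0.6	-4.0
40	H-bond	3SXF	BK5...Y131	-3.8	3.1	-0.7
41	H-bond	2R3P	3SC...L83	-6.1	3.3	-2.8
42	salt-bridge	3MA3	01I...K67	-111.0	102.6	-8.4
43	salt-bridge	4L9I	8PR...D271	-100.3	94.5	-5.8
44	salt-bridge	1NVQ	UCN...E91	-100.0	98.6	-1.4
45	salt-bridge	4JIK	1KO...D148	-115.9	112.2	-3.7
46	salt-bridge	1BX6	BA1...E127	-68.2	67.5	-0.7
47	salt-bridge	4WG4	UWB...E135	-92.6	87.5	-5.1
48	salt-bridge	4MTA	2D2...K67	-106.6	99.4	-7.2
49	salt-bridge	1E9H	INR...K33	-101.5	98.5	-3.0
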