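# Curated library of 49 two-monomer nonbonded interaction motifs between
# protein kinase inhibitors (three-letter ligand IDs) and their interacting
# residues, extracted from chain A of the named PDB entries.
# angle1/angle2: degrees.  For pi-pi rows angle1 is the angle between the two
# ring planes; for H-bond rows angle1/angle2 are the two D-H...A angles of the
# dual hydrogen bond (motif 40 has a single bond).  dist1/dist2: angstrom.
# For H-bond rows these are the donor-acceptor distances; for all other modes
# dist1 is the closest C/N/O heavy-atom contact between the monomers.
# Unicode ellipses/minus signs in the original labels are normalized to ASCII.
motif_no	mode	pdb_id	pair	angle1	angle2	dist1	dist2
1	CH-pi	1H1Q	2A6...A31			3.32
2	CH-pi	4BDB	ODO...L354			3.93
3	CH-pi	2BTS	U32...I10			3.55
4	CH-pi	2XIY	XIY...L174			3.57
5	CH-pi	1UU9	BI3...L88			3.81
6	CH-pi	2IO6	330...I374			4.41
7	CH-pi	4GUE	QCT...L147			3.61
8	CH-pi	3OOG	YTP...A70			3.34
9	CH-pi	4FKO	20K...I10			3.72
10	CH-pi	3QL8	X01...L134			3.23
11	CH-pi	4RC2	3O8...L174			3.43
12	CH-pi	4RC3	3OA...A56			3.27
13	CH-pi	3QX4	X4B...L134			3.61
14	pi-pi	2V7O	DRN...F90	89.64		3.77
15	pi-pi	3I4B	Z48...Y134	6.8		4.31
16	pi-pi	4DGO	0JW...F113	43.85		3.55
17	pi-pi	3QQF	X07...F82	70.14		3.76
18	pi-pi	3B2T	M33...Y566	10.09		3.83
19	pi-pi	3R6X	X84...F82	74.54		3.71
20	pi-pi	4WG4	UWB...Y131	5.57		4.08
21	pi-pi	1PXN	CK6...F82	16.8		3.62
22	pi-pi	3ROY	22Z...F82	68.31		3.75
23	pi-pi	2C6O	4SP...F82	20.3		4.01
24	pi-pi	3RAK	03Z...F82	41.29		3.81
25	pi-pi	4EL9	AFE...F79	19.17		3.48
26	cation-pi	1PXL	CK4...K33			4.62
27	cation-pi	1FGI	SU1...K514			5.15
28	cation-pi	1M2Q	MNX...K68			4.21
29	cation-pi	2VGP	AD6...K180			5.06
30	cation-pi	3OWP	2SB...K72			3.59
31	cation-pi	3SQQ	99Z...K33			5.12
32	cation-pi	3RJC	06Z...K33			4.77
33	cation-pi	3QTW	X3A...K89			3.51
34	H-bond	3SW4	18K...L83	158.59	166.51	2.88	2.94
35	H-bond	3ZLY	YSO...M146	153.12	164.48	2.97	3.26
36	H-bond	3RZB	02Z...L83	143.48	162.20	2.96	3.06
37	H-bond	3RPY	27Z...L83	141.82	167.13	2.89	3.24
38	H-bond	3R28	XA0...L83	155.87	134.34	2.88	2.98
39	H-bond	3QZI	X72...L83	132.02	148.51	2.98	2.98
40	H-bond	3SXF	BK5...Y131	161.45		3.14
41	H-bond	2R3P	3SC...L83	141.41	168.79	2.82	3.35
42	salt-bridge	3MA3	01I...K67			3.38
43	salt-bridge	4L9I	8PR...D271			3.96
44	salt-bridge	1NVQ	UCN...E91			3.48
45	salt-bridge	4JIK	1KO...D148			3.22
46	salt-bridge	1BX6	BA1...E127			5.05
47	salt-bridge	4WG4	UWB...E135			4.16
48	salt-bridge	4MTA	2D2...K67			3.67
49	salt-bridge	1E9H	INR...K33			3.65
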