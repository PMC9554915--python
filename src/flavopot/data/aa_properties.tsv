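# flavopot amino-acid property table, version 1
# volume: residue volume, A^3 (Zamyatnin 1972)
# flexibility: average flexibility index (Bhaskaran & Ponnuswamy 1988)
# hydrophobicity: Kyte-Doolittle hydropathy (1982)
# steric_hindrance: Charton steric parameter (1981)
# polarity_index: Grantham polarity (1974)
# isoelectric_point: Zimmerman pI (1968)
# helix_propensity / sheet_propensity: Chou-Fasman P_alpha / P_beta (1978)
# n_C..n_S: heavy-atom element counts of the side chain (beyond CA)
# n_aromatic_atoms: side-chain aromatic ring atoms
# n_donor_atoms / n_acceptor_atoms: side-chain H-bond donor / acceptor heavy atoms
# class flags are 0/1; classes may overlap (e.g. HIS is positive and aromatic)
name	letter	volume	flexibility	hydrophobicity	steric_hindrance	polarity_index	isoelectric_point	helix_propensity	sheet_propensity	n_C	n_N	n_O	n_S	n_aromatic_atoms	n_donor_atoms	n_acceptor_atoms	polar	apolar	hydrophobic	charged	positive	negative	aromatic	small	hbond_donor	hbond_acceptor
ALA	A	88.6	0.357	1.8	0.52	8.1	6.00	1.42	0.83	1	0	0	0	0	0	0	0	1	1	0	0	0	0	1	0	0
ARG	R	173.4	0.529	-4.5	0.68	10.5	10.76	0.98	0.93	4	3	0	0	0	3	0	1	0	0	1	1	0	0	0	1	0
ASN	N	114.1	0.463	-3.5	0.76	11.6	5.41	0.67	0.89	2	1	1	0	0	1	1	1	0	0	0	0	0	0	1	1	1
ASP	D	111.1	0.511	-3.5	0.76	13.0	2.77	1.01	0.54	2	0	2	0	0	0	2	1	0	0	1	0	1	0	1	0	1
CYS	C	108.5	0.346	2.5	0.62	5.5	5.05	0.70	1.19	1	0	0	1	0	0	0	1	0	1	0	0	0	0	1	0	0
GLN	Q	143.8	0.493	-3.5	0.68	10.5	5.65	1.11	1.10	3	1	1	0	0	1	1	1	0	0	0	0	0	0	0	1	1
GLU	E	138.4	0.497	-3.5	0.68	12.3	3.22	1.51	0.37	3	0	2	0	0	0	2	1	0	0	1	0	1	0	0	0	1
GLY	G	60.1	0.544	-0.4	0.00	9.0	5.97	0.57	0.75	0	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0
HIS	H	153.2	0.323	-3.2	0.70	10.4	7.59	1.00	0.87	4	2	0	0	5	1	1	1	0	0	1	1	0	1	0	1	1
ILE	I	166.7	0.462	4.5	1.02	5.2	6.02	1.08	1.60	4	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0
LEU	L	166.7	0.365	3.8	0.98	4.9	5.98	1.21	1.30	4	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0
LYS	K	168.6	0.466	-3.9	0.68	11.3	9.74	1.16	0.74	4	1	0	0	0	1	0	1	0	0	1	1	0	0	0	1	0
MET	M	162.9	0.295	1.9	0.78	5.7	5.74	1.45	1.05	3	0	0	1	0	0	0	0	1	1	0	0	0	0	0	0	0
PHE	F	189.9	0.314	2.8	0.70	5.2	5.48	1.13	1.38	7	0	0	0	6	0	0	0	1	1	0	0	0	1	0	0	0
PRO	P	112.7	0.509	-1.6	0.36	8.0	6.30	0.57	0.55	3	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0
SER	S	89.0	0.507	-0.8	0.53	9.2	5.68	0.77	0.75	1	0	1	0	0	1	1	1	0	0	0	0	0	0	1	1	1
THR	T	116.1	0.444	-0.7	0.63	8.6	5.66	0.83	1.19	2	0	1	0	0	1	1	1	0	0	0	0	0	0	1	1	1
TRP	W	227.8	0.305	-0.9	0.70	5.4	5.89	1.08	1.37	9	1	0	0	9	1	0	0	1	0	0	0	0	1	0	1	0
TYR	Y	193.6	0.420	-1.3	0.70	6.2	5.66	0.69	1.47	7	0	1	0	6	1	1	1	0	0	0	0	0	1	0	1	1
VAL	V	140.0	0.386	4.2	0.76	5.9	5.96	1.06	1.70	3	0	0	0	0	0	0	0	1	1	0	0	0	0	1	0	0
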