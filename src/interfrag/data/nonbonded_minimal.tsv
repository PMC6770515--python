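# Representative Amber-style non-bonded parameters (charges in e,
# r_star in Angstrom, eps in kcal/mol).  Backbone atoms carry generic
# internal-residue values; side chains are listed for the residues the
# extraction logic treats specially.  ALL denotes any standard residue.
res_name	atom_name	q	r_star	eps
ALL	N	-0.4157	1.8240	0.1700
ALL	H	0.2719	0.6000	0.0157
ALL	CA	0.0337	1.9080	0.1094
ALL	HA	0.0823	1.3870	0.0157
ALL	C	0.5973	1.9080	0.0860
ALL	O	-0.5679	1.6612	0.2100
ALL	OXT	-0.8055	1.6612	0.2100
GLY	HA2	0.0698	1.3870	0.0157
GLY	HA3	0.0698	1.3870	0.0157
ALA	CB	-0.1825	1.9080	0.1094
ALA	HB1	0.0603	1.4870	0.0157
ALA	HB2	0.0603	1.4870	0.0157
ALA	HB3	0.0603	1.4870	0.0157
CYS	CB	-0.1231	1.9080	0.1094
CYS	HB2	0.1112	1.3870	0.0157
CYS	HB3	0.1112	1.3870	0.0157
CYS	SG	-0.3119	2.0000	0.2500
CYS	HG	0.1933	0.6000	0.0157
SER	CB	0.2117	1.9080	0.1094
SER	HB2	0.0352	1.3870	0.0157
SER	HB3	0.0352	1.3870	0.0157
SER	OG	-0.6546	1.7210	0.2104
SER	HG	0.4275	0.0000	0.0000
ASP	CB	-0.0303	1.9080	0.1094
ASP	HB2	-0.0122	1.4870	0.0157
ASP	HB3	-0.0122	1.4870	0.0157
ASP	CG	0.7994	1.9080	0.0860
ASP	OD1	-0.8014	1.6612	0.2100
ASP	OD2	-0.8014	1.6612	0.2100
GLU	CB	0.0560	1.9080	0.1094
GLU	HB2	-0.0173	1.4870	0.0157
GLU	HB3	-0.0173	1.4870	0.0157
GLU	CG	0.0136	1.9080	0.1094
GLU	HG2	-0.0425	1.4870	0.0157
GLU	HG3	-0.0425	1.4870	0.0157
GLU	CD	0.8054	1.9080	0.0860
GLU	OE1	-0.8188	1.6612	0.2100
GLU	OE2	-0.8188	1.6612	0.2100
LYS	CB	-0.0094	1.9080	0.1094
LYS	CG	0.0187	1.9080	0.1094
LYS	CD	-0.0479	1.9080	0.1094
LYS	CE	-0.0143	1.9080	0.1094
LYS	NZ	-0.3854	1.8240	0.1700
LYS	HZ1	0.3400	0.6000	0.0157
LYS	HZ2	0.3400	0.6000	0.0157
LYS	HZ3	0.3400	0.6000	0.0157
HIS	CB	-0.0074	1.9080	0.1094
HIS	CG	0.1868	1.9080	0.0860
HIS	ND1	-0.5432	1.8240	0.1700
HIS	HD1	0.3821	0.6000	0.0157
HIS	CD2	-0.2207	1.9080	0.0860
HIS	HD2	0.1862	1.4090	0.0150
HIS	CE1	0.1635	1.9080	0.0860
HIS	HE1	0.1435	1.3590	0.0150
HIS	NE2	-0.2795	1.8240	0.1700
HIS	HE2	0.3339	0.6000	0.0157
ACE	CH3	-0.3662	1.9080	0.1094
ACE	HH31	0.1123	1.4870	0.0157
ACE	HH32	0.1123	1.4870	0.0157
ACE	HH33	0.1123	1.4870	0.0157
ACE	C	0.5972	1.9080	0.0860
ACE	O	-0.5679	1.6612	0.2100
NME	N	-0.4157	1.8240	0.1700
NME	H	0.2719	0.6000	0.0157
NME	CH3	-0.1490	1.9080	0.1094
NME	HH31	0.0976	1.3870	0.0157
NME	HH32	0.0976	1.3870	0.0157
NME	HH33	0.0976	1.3870	0.0157
WAT	O	-0.8340	1.7683	0.1520
WAT	OW	-0.8340	1.7683	0.1520
WAT	H1	0.4170	0.0000	0.0000
WAT	H2	0.4170	0.0000	0.0000
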