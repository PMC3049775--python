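# Simplified additive nonbonded parameter set at reduced atom detail
# (heavy atoms + amide/cap hydrogens only; carbon LJ parameters are
# united-atom-like since aliphatic/aromatic hydrogens are implicit).
# Charges are chosen so that each
# residue template carries its exact formal charge.  Neutral-group charges
# (backbone amide dipoles, caps, Gln/Ser/neutral-His sidechains) are scaled
# by 0.5 to emulate aqueous dielectric screening of dipolar interactions in
# the absence of explicit solvent; ionizable sidechains keep integral formal
# charges.  LJ parameters are generic per-element values.  Columns:
# template	atom	element	charge_e	epsilon_kcalmol	rmin_half_A	class
BB	N	N	-0.200	0.170	1.85	bb
BB	HN	H	0.125	0.046	0.22	h
BB	CA	C	0.050	0.120	2.10	bb
BB	C	C	0.275	0.120	2.10	bb
BB	O	O	-0.250	0.120	1.70	bb
ACE	CAY	C	0.000	0.120	2.10	sc
ACE	CY	C	0.250	0.120	2.10	sc
ACE	OY	O	-0.250	0.120	1.70	sc
NH2	NT	N	-0.150	0.170	1.85	sc
NH2	HT1	H	0.075	0.046	0.22	h
NH2	HT2	H	0.075	0.046	0.22	h
ALA	CB	C	0.000	0.120	2.10	sc
GLY	-	-	-	-	-	-
VAL	CB	C	0.000	0.120	2.10	sc
VAL	CG1	C	0.000	0.120	2.10	sc
VAL	CG2	C	0.000	0.120	2.10	sc
LEU	CB	C	0.000	0.120	2.10	sc
LEU	CG	C	0.000	0.120	2.10	sc
LEU	CD1	C	0.000	0.120	2.10	sc
LEU	CD2	C	0.000	0.120	2.10	sc
PHE	CB	C	0.000	0.120	2.10	sc
PHE	CG	C	0.000	0.120	2.10	sc
PHE	CD1	C	0.000	0.120	2.10	sc
PHE	CD2	C	0.000	0.120	2.10	sc
PHE	CE1	C	0.000	0.120	2.10	sc
PHE	CE2	C	0.000	0.120	2.10	sc
PHE	CZ	C	0.000	0.120	2.10	sc
SER	CB	C	0.025	0.120	2.10	sc
SER	OG	O	-0.025	0.120	1.70	sc
GLN	CB	C	0.000	0.120	2.10	sc
GLN	CG	C	0.000	0.120	2.10	sc
GLN	CD	C	0.275	0.120	2.10	sc
GLN	OE1	O	-0.275	0.120	1.70	sc
GLN	NE2	N	0.000	0.170	1.85	sc
LYS	CB	C	0.00	0.120	2.10	sc
LYS	CG	C	0.00	0.120	2.10	sc
LYS	CD	C	0.00	0.120	2.10	sc
LYS	CE	C	0.25	0.120	2.10	sc
LYS	NZ	N	0.75	0.170	1.85	sc
GLU	CB	C	0.00	0.120	2.10	sc
GLU	CG	C	-0.10	0.120	2.10	sc
GLU	CD	C	0.50	0.120	2.10	sc
GLU	OE1	O	-0.70	0.120	1.70	sc
GLU	OE2	O	-0.70	0.120	1.70	sc
ASP	CB	C	-0.10	0.120	2.10	sc
ASP	CG	C	0.50	0.120	2.10	sc
ASP	OD1	O	-0.70	0.120	1.70	sc
ASP	OD2	O	-0.70	0.120	1.70	sc
HIP	CB	C	0.00	0.120	2.10	sc
HIP	CG	C	0.10	0.120	2.10	sc
HIP	ND1	N	0.20	0.170	1.85	sc
HIP	CD2	C	0.10	0.120	2.10	sc
HIP	CE1	C	0.35	0.120	2.10	sc
HIP	NE2	N	0.25	0.170	1.85	sc
HIE	CB	C	0.000	0.120	2.10	sc
HIE	CG	C	0.050	0.120	2.10	sc
HIE	ND1	N	-0.200	0.170	1.85	sc
HIE	CD2	C	0.050	0.120	2.10	sc
HIE	CE1	C	0.150	0.120	2.10	sc
HIE	NE2	N	-0.050	0.170	1.85	sc
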