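# Physicochemical classes per (residue, heavy atom).
# classes: comma-separated subset of
#   positive,negative,aromatic,hydrophobic,donor,acceptor   ("-" = none)
# The atoms listed here (minus OXT) are also the expected heavy-atom
# complement used by the missing-atom chain filter.
# Conventions: His ring nitrogens are treated as positive (protonation
# unknown); hydrophobic = carbon/thioether atoms not bonded to N or O.
ALA	N	donor
ALA	CA	-
ALA	C	-
ALA	O	acceptor
ALA	CB	hydrophobic
ARG	N	donor
ARG	CA	-
ARG	C	-
ARG	O	acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	-
ARG	NE	positive,donor
ARG	CZ	-
ARG	NH1	positive,donor
ARG	NH2	positive,donor
ASN	N	donor
ASN	CA	-
ASN	C	-
ASN	O	acceptor
ASN	CB	hydrophobic
ASN	CG	-
ASN	OD1	acceptor
ASN	ND2	donor
ASP	N	donor
ASP	CA	-
ASP	C	-
ASP	O	acceptor
ASP	CB	hydrophobic
ASP	CG	-
ASP	OD1	negative,acceptor
ASP	OD2	negative,acceptor
CYS	N	donor
CYS	CA	-
CYS	C	-
CYS	O	acceptor
CYS	CB	hydrophobic
CYS	SG	donor,acceptor
GLN	N	donor
GLN	CA	-
GLN	C	-
GLN	O	acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	-
GLN	OE1	acceptor
GLN	NE2	donor
GLU	N	donor
GLU	CA	-
GLU	C	-
GLU	O	acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	-
GLU	OE1	negative,acceptor
GLU	OE2	negative,acceptor
GLY	N	donor
GLY	CA	-
GLY	C	-
GLY	O	acceptor
HIS	N	donor
HIS	CA	-
HIS	C	-
HIS	O	acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	aromatic,positive,donor,acceptor
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	aromatic,positive,donor,acceptor
ILE	N	donor
ILE	CA	-
ILE	C	-
ILE	O	acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
LEU	N	donor
LEU	CA	-
LEU	C	-
LEU	O	acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LYS	N	donor
LYS	CA	-
LYS	C	-
LYS	O	acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	-
LYS	NZ	positive,donor
MET	N	donor
MET	CA	-
MET	C	-
MET	O	acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	hydrophobic
MET	CE	hydrophobic
PHE	N	donor
PHE	CA	-
PHE	C	-
PHE	O	acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PRO	N	-
PRO	CA	-
PRO	C	-
PRO	O	acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	-
SER	N	donor
SER	CA	-
SER	C	-
SER	O	acceptor
SER	CB	-
SER	OG	donor,acceptor
THR	N	donor
THR	CA	-
THR	C	-
THR	O	acceptor
THR	CB	-
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
TRP	N	donor
TRP	CA	-
TRP	C	-
TRP	O	acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic,hydrophobic
TRP	CD1	aromatic
TRP	CD2	aromatic,hydrophobic
TRP	NE1	aromatic,donor
TRP	CE2	aromatic
TRP	CE3	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TYR	N	donor
TYR	CA	-
TYR	C	-
TYR	O	acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic,hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CZ	aromatic
TYR	OH	donor,acceptor
VAL	N	donor
VAL	CA	-
VAL	C	-
VAL	O	acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
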